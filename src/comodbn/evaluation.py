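"""Calibration and discrimination evaluation of a learned DBN.

Observed and simulated follow-ups are reduced to event records (time of
outcome onset, or censoring), compared as Kaplan-Meier curves with a
log-rank test (calibration), and scored for discrimination with
time-dependent AU-ROC / AUC-PR at a two-year grid, integrated by unweighted
averaging.  The per-subject risk score is one minus the normalised area
under the subject's own Kaplan-Meier curve across the simulation
repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score

from .schema_io import PanelDataset
from .simulation import SimulatedCohort, simulate_population
from .structure_learning import DBNModel

logger = logging.getLogger(__name__)

__all__ = [
    "EventRecords",
    "SurvivalCurve",
    "MetricSeries",
    "EvalConfig",
    "EvaluationResult",
    "extract_events",
    "km_curve",
    "logrank",
    "risk_score",
    "td_auroc",
    "td_aucpr",
    "integrate_metric",
    "evaluate_model",
]


@dataclass
class EventRecords:
    """Event/censoring records: one row per subject (and repetition)."""

    frame: pd.DataFrame  # columns: subject_id, rep, time, event
    outcome: str
    n_prevalent_excluded: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=bool)


def _events_from_waves(df: pd.DataFrame, outcome: str, id_cols: list[str],
                       time_col: str) -> tuple[pd.DataFrame, int]:
    """First-onset extraction shared by panels and simulated cohorts.

    Rows with a missing outcome value do not extend a subject's observation:
    follow-up is censored at the last wave with an observed value.
    """
    d = df[id_cols + [time_col, outcome]].copy()
    d = d[d[outcome].notna()]
    d[outcome] = d[outcome].astype(int)
    d = d.sort_values(id_cols + [time_col])
    g = d.groupby(id_cols, sort=False)
    first = g.first()
    prevalent = first[first[outcome] == 1].index
    n_prev = len(prevalent)

    agg = g.agg(last_time=(time_col, "max"))
    onset = d[d[outcome] == 1].groupby(id_cols, sort=False)[time_col].min()
    agg["event"] = agg.index.isin(onset.index)
    agg["time"] = np.where(agg["event"], onset.reindex(agg.index), agg["last_time"])
    agg = agg.drop(index=prevalent)
    out = agg.reset_index()[id_cols + ["time", "event"]]
    return out, n_prev


def extract_events(source: SimulatedCohort | PanelDataset, outcome: str) -> EventRecords:
    """Reduce follow-ups to first-onset event records for one outcome.

    The event time is the first wave offset at which the outcome is "yes";
    subjects already positive at baseline (prevalent cases) are excluded
    from the onset analysis; everyone else is censored at their last
    observed or simulated offset.  For the survival outcome the event is
    death, recorded at the offset of the wave where survival turns yes.
    """
    if isinstance(source, SimulatedCohort):
        if outcome not in source.columns:
            raise KeyError(f"unknown outcome {outcome!r}")
        frame, n_prev = _events_from_waves(
            source.frame, outcome, ["subject_id", "rep"], "offset_years")
    else:
        cat = source.catalog
        if outcome not in cat.outcome_names and outcome != cat.survival_name:
            raise KeyError(f"unknown outcome {outcome!r}")
        d = source.data.copy()
        d["offset_years"] = 2.0 * d["wave"]
        frame, n_prev = _events_from_waves(d, outcome, ["subject_id"], "offset_years")
        frame = frame.assign(rep=0)[["subject_id", "rep", "time", "event"]]
    if n_prev:
        logger.info("extract_events(%s): excluded %d baseline-prevalent subject(s)",
                    outcome, n_prev)
    return EventRecords(frame, outcome, n_prev)


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood pointwise confidence band."""

    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray  # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def area(self, horizon: float) -> float:
        """Integral of S over [0, horizon] (step integration)."""
        ts = np.concatenate(([0.0], self.times[self.times <= horizon], [horizon]))
        svals = np.concatenate(([1.0], self.survival[self.times <= horizon]))
        return float(np.sum(np.diff(ts) * svals))


def _km_arrays(times: np.ndarray, events: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Product-limit ingredients: distinct event times, S(t), at-risk, events.

    Ties at equal times follow the standard convention: events are processed
    before censorings (a subject censored at t is still at risk for an event
    at t).
    """
    order = np.argsort(times, kind="stable")
    ts, ev = times[order], events[order]
    etimes, d = np.unique(ts[ev], return_counts=True)
    d = d.astype(float)
    # at risk at t: subjects whose observation time is >= t
    at_risk = len(ts) - np.searchsorted(ts, etimes, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return etimes, surv, at_risk.astype(float), d


def km_curve(records: EventRecords, alpha: float = 0.05) -> SurvivalCurve:
    """Kaplan-Meier estimator with the log-transformed Greenwood interval."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    times, surv, n, d = _km_arrays(records.times, records.events)

    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n > d, d / (n * (n - d)), np.inf)
    cum = np.cumsum(inc)
    with np.errstate(invalid="ignore"):
        var = surv**2 * cum  # 0 * inf at S = 0 -> masked below
    z = norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_log = np.sqrt(cum)
        lo = np.where(surv > 0, np.exp(np.log(np.maximum(surv, 1e-300)) - z * se_log), 0.0)
        hi = np.where(surv > 0, np.exp(np.log(np.maximum(surv, 1e-300)) + z * se_log), 0.0)
    return SurvivalCurve(
        times=times, survival=surv, at_risk=n, n_events=d,
        variance=np.where(np.isfinite(var), var, 0.0),
        ci_lower=np.clip(lo, 0.0, 1.0), ci_upper=np.clip(hi, 0.0, 1.0),
        censor_times=np.sort(records.times[~records.events]),
    )


def logrank(records_a: EventRecords, records_b: EventRecords) -> tuple[float, float]:
    """Two-group log-rank chi-squared statistic and p-value.

    With no events in either group the curves are trivially equal: returns
    (0, 1) with a warning flag in the log.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not records_a.events.any() and not records_b.events.any():
        logger.warning("logrank: no events in either group; p = 1")
        return 0.0, 1.0
    res = logrank_test(records_a.times, records_b.times,
                       event_observed_A=records_a.events,
                       event_observed_B=records_b.events)
    return float(res.test_statistic), float(res.p_value)


def risk_score(rep_records: EventRecords, horizon: float) -> float:
    """Per-subject predicted risk: 1 - (area under the subject's KM curve) / horizon.

    The Kaplan-Meier curve is built over the subject's simulation
    repetitions (censoring at the horizon or earlier death); the normalised
    complement of its area is a bounded risk in [0, 1], 0 when no repetition
    has an event and 1 when every repetition has the event at time zero.
    """
    if len(rep_records) == 0:
        raise ValueError("need at least one repetition")
    return _risk_from_arrays(rep_records.times, rep_records.events, horizon)


def _risk_from_arrays(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    over = times > horizon
    times = np.where(over, horizon, times)
    events = events & ~over
    if not events.any():
        return 0.0
    etimes, surv, _, _ = _km_arrays(times, events)
    ts = np.concatenate(([0.0], etimes, [horizon]))
    svals = np.concatenate(([1.0], surv))
    area = float(np.sum(np.diff(ts) * svals))
    return 1.0 - area / horizon


def _classify(records: EventRecords, t: float) -> tuple[pd.Series, pd.DataFrame]:
    """Cumulative-cases / event-free-controls classification at time t.

    Positives experienced the event at or before t; negatives are event-free
    and still under observation at t; subjects censored before t are
    excluded.
    """
    f = records.frame
    pos = f["event"] & (f["time"] <= t)
    neg = f["time"] >= t
    neg &= ~pos
    keep = pos | neg
    return pos[keep], f[keep]


def td_auroc(risks: pd.Series, records: EventRecords, t: float) -> tuple[float, int, int]:
    """Time-dependent AU-ROC at t: P(risk_pos > risk_neg) + P(tie)/2.

    Returns (auroc, n_positive, n_total); NaN with a flag when either class
    is empty.
    """
    pos, kept = _classify(records, t)
    scores = risks.reindex(kept["subject_id"]).to_numpy(dtype=float)
    y = pos.to_numpy()
    n_pos, n_tot = int(y.sum()), len(y)
    if n_pos == 0 or n_pos == n_tot:
        logger.warning("td_auroc undefined at t=%s (n_pos=%d, n=%d)", t, n_pos, n_tot)
        return float("nan"), n_pos, n_tot
    ranks = rankdata(scores)  # average ranks give the half-credit for ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * (n_tot - n_pos))
    return float(auc), n_pos, n_tot


def td_aucpr(risks: pd.Series, records: EventRecords, t: float) -> tuple[float, int, int]:
    """Time-dependent AUC-PR at t (interpolation-free step integration)."""
    pos, kept = _classify(records, t)
    scores = risks.reindex(kept["subject_id"]).to_numpy(dtype=float)
    y = pos.to_numpy()
    n_pos, n_tot = int(y.sum()), len(y)
    if n_pos == 0:
        logger.warning("td_aucpr undefined at t=%s (no positives)", t)
        return float("nan"), n_pos, n_tot
    return float(average_precision_score(y, scores)), n_pos, n_tot


def integrate_metric(values) -> float:
    """Unweighted mean of the defined (non-NaN) per-time metric values."""
    vals = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no defined time points to integrate")
    return float(vals.mean())


@dataclass
class MetricSeries:
    """Per-time and integrated discrimination metrics for one outcome."""

    outcome: str
    times: list[float]
    auroc: list[float]
    aucpr: list[float]
    n_positive: list[int]
    n_total: list[int]

    @property
    def positive_rate(self) -> list[float]:
        return [p / t if t else float("nan") for p, t in zip(self.n_positive, self.n_total)]

    @property
    def iauroc(self) -> float:
        return integrate_metric(self.auroc)

    @property
    def iaucpr(self) -> float:
        return integrate_metric(self.aucpr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "outcome": self.outcome, "t": self.times, "auroc": self.auroc,
            "aucpr": self.aucpr, "n_positive": self.n_positive,
            "n_total": self.n_total, "positive_rate": self.positive_rate,
        })


@dataclass
class EvalConfig:
    n_reps: int = 100
    horizon_years: float = 12.0
    comorbidity_eval_horizon: float = 8.0
    survival_eval_horizon: float = 4.0
    grid_step: float = 2.0
    seed: int = 0


@dataclass
class EvaluationResult:
    curves: dict  # outcome -> (observed curve, simulated curve, logrank stat, p)
    metrics: dict  # outcome -> MetricSeries
    n_subjects: int
    cohort: SimulatedCohort | None = None


def _complete_baseline(panel: PanelDataset) -> pd.DataFrame:
    """Test subjects with no missing variable at baseline (simulation input)."""
    base = panel.baseline()
    needed = [c for c in panel.variable_columns]
    ok = base[needed].notna().all(axis=1)
    return base[ok]


def evaluate_model(model: DBNModel, test: PanelDataset,
                   config: EvalConfig | None = None) -> EvaluationResult:
    """End-to-end calibration + discrimination evaluation on a test panel.

    Simulates ``n_reps`` follow-ups per complete-baseline test subject,
    compares observed and simulated (all repetitions pooled) Kaplan-Meier
    curves per outcome with the log-rank test, and computes time-dependent
    AU-ROC / AUC-PR on the per-subject risk scores at the two-year grid (up
    to 8 years for the comorbidities, 4 years for death).
    """
    cfg = config or EvalConfig()
    cat = model.catalog
    base = _complete_baseline(test)
    logger.info("evaluating on %d complete-baseline subjects (of %d)",
                len(base), test.n_subjects)
    cohort = simulate_population(model, base, n_reps=cfg.n_reps,
                                 horizon_years=cfg.horizon_years, seed=cfg.seed)
    kept = PanelDataset(test.data[test.data["subject_id"].isin(base["subject_id"])],
                        cat, stage=test.stage)

    curves, metrics = {}, {}
    for outcome in cat.outcome_names + [cat.survival_name]:
        observed = extract_events(kept, outcome)
        simulated = extract_events(cohort, outcome)
        stat, p = logrank(observed, simulated)
        curves[outcome] = (km_curve(observed), km_curve(simulated), stat, p)

        eval_h = (cfg.survival_eval_horizon if outcome == cat.survival_name
                  else cfg.comorbidity_eval_horizon)
        grid = list(np.arange(cfg.grid_step, eval_h + 1e-9, cfg.grid_step))
        sf = simulated.frame.sort_values("subject_id")
        sids = sf["subject_id"].to_numpy()
        times_arr = sf["time"].to_numpy(dtype=float)
        events_arr = sf["event"].to_numpy(dtype=bool)
        uniq, starts = np.unique(sids, return_index=True)
        bounds = np.append(starts, len(sids))
        risks = pd.Series(
            [_risk_from_arrays(times_arr[a:b], events_arr[a:b], eval_h)
             for a, b in zip(bounds[:-1], bounds[1:])], index=uniq)
        # subjects prevalent in simulation are also prevalent in reality
        # (shared baseline), so the observed records line up by construction
        aurocs, aucprs, npos, ntot = [], [], [], []
        for t in grid:
            a, n_p, n_t = td_auroc(risks, observed, t)
            pr, _, _ = td_aucpr(risks, observed, t)
            aurocs.append(a)
            aucprs.append(pr)
            npos.append(n_p)
            ntot.append(n_t)
        metrics[outcome] = MetricSeries(outcome, grid, aurocs, aucprs, npos, ntot)
    return EvaluationResult(curves, metrics, len(base), cohort)
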