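"""Panel preprocessing: alignment, inclusion filters, imputation, quantisation, split.

The raw panel carries original wave numbers and missing cells.  Preprocessing
(1) keeps each subject's initial run of consecutive waves and re-indexes the
first as baseline 0, (2) applies the three inclusion filters (two or more
visits, baseline age above 40, not all biomarkers missing), (3) imputes
dynamic variables within subject (linear interpolation for interior gaps of
continuous series, next/last-observation propagation at the edges and for
categorical or single-observation series, training median/mode as the last
resort), (4) quantises continuous values into the catalog's clinical levels,
and (5) splits subjects 75/25 stratified by baseline-age level, with
Kruskal-Wallis / chi-squared balance checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema_io import PanelDataset, QuantizationScheme, VariableCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationStats",
    "SplitResult",
    "align_waves",
    "filter_subjects",
    "impute_panel",
    "discretize",
    "stratified_split",
    "check_balance",
    "preprocess_pipeline",
]

# Columns that are never imputed and never blanked.
def _protected(catalog: VariableCatalog) -> set[str]:
    return set(catalog.outcome_names) | {catalog.survival_name, catalog.time_name,
                                         "Sex", "Baseline age"}


def align_waves(panel: PanelDataset) -> PanelDataset:
    """Keep each subject's longest initial run of consecutive waves.

    The first participated wave becomes baseline (wave 0); later indices are
    consecutive.  Time since baseline (years) is two per wave step.  Subjects
    with zero rows are dropped with a warning (vacuously true here since they
    have no rows to begin with).
    """
    df = panel.data.sort_values(["subject_id", "wave"]).reset_index(drop=True)
    first = df.groupby("subject_id")["wave"].transform("min")
    pos = df.groupby("subject_id").cumcount()
    keep = df["wave"] == first + pos  # contiguous prefix of the wave sequence
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("align_waves: dropped %d non-consecutive visit rows", n_drop)
    out = df[keep].copy()
    out["wave"] = out.groupby("subject_id").cumcount()
    out[panel.catalog.time_name] = 2.0 * out["wave"]
    return PanelDataset(out.reset_index(drop=True), panel.catalog, stage="raw")


def filter_subjects(panel: PanelDataset) -> PanelDataset:
    """Apply the three inclusion criteria.

    (i) at least two available visits; (ii) baseline age greater than 40
    years; (iii) at least one biomarker observed in at least one wave.
    Criteria (ii) / (iii) are skipped when the catalog has no baseline-age /
    biomarker variables.
    """
    df = panel.data
    counts = df.groupby("subject_id")["wave"].count()
    ok = counts[counts >= 2].index

    if "Baseline age" in df.columns:
        base = df.sort_values(["subject_id", "wave"]).groupby("subject_id").first()
        age_ok = base.index[base["Baseline age"] > 40]
        ok = ok.intersection(age_ok)

    biom = [b for b in panel.catalog.biomarker_names if b in df.columns]
    if biom:
        any_obs = df.groupby("subject_id")[biom].apply(lambda g: g.notna().any().any())
        ok = ok.intersection(any_obs[any_obs].index)

    out = df[df["subject_id"].isin(ok)].reset_index(drop=True)
    logger.info("filter_subjects: kept %d of %d subjects", len(ok), counts.size)
    return PanelDataset(out, panel.catalog, stage=panel.stage)


@dataclass
class ImputationStats:
    """Training-population fallback values: median (continuous/ordinal) or mode."""

    values: dict[str, object] = field(default_factory=dict)
    fitted_on_train_only: bool = True

    @classmethod
    def fit(cls, panel: PanelDataset) -> "ImputationStats":
        cat = panel.catalog
        skip = _protected(cat)
        values: dict[str, object] = {}
        for spec in cat:
            name = spec.name
            if name in skip or name not in panel.data.columns:
                continue
            col = panel.data[name].dropna()
            if len(col) == 0:
                continue
            if spec.domain_kind == "categorical":
                values[name] = col.mode().iloc[0]
            else:
                values[name] = float(col.astype(float).median())
        return cls(values)


def impute_panel(panel: PanelDataset, stats: ImputationStats) -> PanelDataset:
    """Hybrid within-subject imputation.

    Dynamic continuous series: interior gaps are linearly interpolated on the
    time axis; leading gaps take the next observation (NOCB), trailing gaps
    the last (LOCF).  Dynamic categorical/ordinal series and continuous
    series with a single observation use propagation only.  A variable with
    no observation at all for a subject — and any missing static variable —
    falls back to the training median/mode.  Outcome, survival, sex,
    baseline age and time-since-baseline columns are never touched.
    """
    cat = panel.catalog
    skip = _protected(cat)
    df = panel.data.sort_values(["subject_id", "wave"]).reset_index(drop=True)
    for spec in cat:
        name = spec.name
        if name in skip or name not in df.columns:
            continue
        col = df[name]
        if not col.isna().any():
            continue
        if name not in stats.values:
            raise ValueError(f"imputation stats lack a value for {name!r}")
        g = df.groupby("subject_id")[name]
        if spec.temporal_kind == "dynamic" and spec.domain_kind == "continuous":
            # interpolation needs >=2 observations; single-observation
            # series are handled by the propagation below
            filled = g.transform(lambda s: s.astype(float).interpolate(
                method="linear", limit_area="inside"))
        else:
            filled = col
        with pd.option_context("future.no_silent_downcasting", True):
            filled = filled.groupby(df["subject_id"]).transform(lambda s: s.bfill().ffill())
            filled = filled.fillna(stats.values[name])
        df[name] = filled
    out = PanelDataset(df, cat, stage="imputed")
    non_outcome = [c for c in out.variable_columns
                   if c not in cat.outcome_names and c != cat.survival_name]
    assert not out.data[non_outcome].isna().any().any()
    return out


def discretize(panel: PanelDataset, scheme: QuantizationScheme | None = None) -> PanelDataset:
    """Map continuous values to quantisation levels and labels to codes.

    Thresholds belong to the upper level (half-open [a, b) intervals).
    Idempotent on already-discrete panels.
    """
    if panel.stage == "discrete":
        return panel
    cat = panel.catalog
    scheme = scheme or cat.scheme
    df = panel.data.copy()
    for spec in cat:
        name = spec.name
        if name not in df.columns:
            continue
        col = df[name]
        if spec.domain_kind == "categorical":
            codes = col.map(lambda v: np.nan if pd.isna(v) else spec.levels.index(str(v)))
        else:
            rule = scheme[name]
            codes = col.map(lambda v: np.nan if pd.isna(v)
                            else int(np.searchsorted(rule.thresholds, float(v), side="right")))
        df[name] = pd.array(codes, dtype="Int64")
    return PanelDataset(df, cat, stage="discrete")


@dataclass
class SplitResult:
    train: PanelDataset
    test: PanelDataset
    balance: pd.DataFrame


def stratified_split(panel: PanelDataset, frac: float = 0.75,
                     seed: int = 0) -> SplitResult:
    """Subject-level split stratified by baseline-age level.

    Within each stratum, round(frac * n) subjects go to train; strata with
    fewer than two subjects go wholly to train with a warning.  Without a
    baseline-age variable the whole panel is a single stratum.
    """
    cat = panel.catalog
    base = panel.baseline().set_index("subject_id")
    if "Baseline age" in base.columns:
        ages = base["Baseline age"].astype(float)
        if panel.stage == "discrete":
            strata = ages
        else:
            rule = cat.scheme["Baseline age"]
            strata = ages.map(rule.level)
    else:
        strata = pd.Series(0, index=base.index)

    rng = np.random.default_rng(seed)
    train_ids: list = []
    for _, members in strata.groupby(strata):
        ids = np.array(sorted(members.index))
        if len(ids) < 2:
            logger.warning("stratum with %d subject(s) assigned wholly to train", len(ids))
            train_ids.extend(ids)
            continue
        n_train = int(round(frac * len(ids)))
        order = rng.permutation(len(ids))
        train_ids.extend(ids[order[:n_train]])
    train_mask = panel.data["subject_id"].isin(train_ids)
    train = PanelDataset(panel.data[train_mask].reset_index(drop=True), cat, stage=panel.stage)
    test = PanelDataset(panel.data[~train_mask].reset_index(drop=True), cat, stage=panel.stage)
    balance = check_balance(train, test)
    return SplitResult(train, test, balance)


def check_balance(train: PanelDataset, test: PanelDataset) -> pd.DataFrame:
    """Train-vs-test baseline balance table.

    Kruskal-Wallis for continuous/ordinal variables, chi-squared (asymptotic,
    no continuity correction) for categorical ones.  A degenerate variable
    (single observed value overall) is recorded with p = 1 and a flag.
    """
    if len(train.data) == 0 or len(test.data) == 0:
        raise ValueError("both panels must be non-empty")
    cat = train.catalog
    a = train.baseline()
    b = test.baseline()
    rows = []
    for spec in cat:
        name = spec.name
        if name not in a.columns or name == cat.time_name:
            continue
        x = a[name].dropna()
        y = b[name].dropna()
        if len(x) == 0 or len(y) == 0:
            continue
        degenerate = pd.concat([x, y]).nunique() < 2
        if degenerate:
            rows.append((name, "degenerate", 1.0, True))
            continue
        if spec.domain_kind == "categorical" and train.stage != "discrete":
            tab = pd.crosstab(
                pd.concat([x, y]),
                np.r_[np.zeros(len(x)), np.ones(len(y))])
            _, p, _, _ = stats.chi2_contingency(tab, correction=False)
            rows.append((name, "chi2", float(p), False))
        elif spec.domain_kind == "categorical":
            tab = pd.crosstab(pd.concat([x, y]).astype(int),
                              np.r_[np.zeros(len(x)), np.ones(len(y))])
            _, p, _, _ = stats.chi2_contingency(tab, correction=False)
            rows.append((name, "chi2", float(p), False))
        else:
            _, p = stats.kruskal(x.astype(float), y.astype(float))
            rows.append((name, "kruskal-wallis", float(p), False))
    return pd.DataFrame(rows, columns=["variable", "test", "p_value", "degenerate"])


def preprocess_pipeline(raw: PanelDataset, frac: float = 0.75, seed: int = 0
                        ) -> tuple[SplitResult, SplitResult, ImputationStats]:
    """Raw panel -> aligned, filtered, imputed, discretised train/test split.

    Subjects are split before imputation so that the fallback medians/modes
    are fitted on training subjects only.  Returns the discrete-stage split,
    the imputed-stage (continuous) split, and the fitted statistics.
    """
    aligned = filter_subjects(align_waves(raw))
    pre_split = stratified_split(aligned, frac=frac, seed=seed)
    stats_ = ImputationStats.fit(pre_split.train)
    train_imp = impute_panel(pre_split.train, stats_)
    test_imp = impute_panel(pre_split.test, stats_)
    train_disc = discretize(train_imp)
    test_disc = discretize(test_imp)
    disc = SplitResult(train_disc, test_disc, check_balance(train_disc, test_disc))
    imp = SplitResult(train_imp, test_imp, pre_split.balance)
    return disc, imp, stats_
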