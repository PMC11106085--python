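"""In-silico follow-up simulation from a learned DBN.

Starting from a subject's complete baseline record, the simulator advances in
two-year steps, at each step sampling every slice-t variable from its CPT
given the previous wave, the static variables and the deterministically
advanced time-since-baseline level, then sampling survival.  Outcomes are
clamped to "yes" once entered (disease onset is defined as "experienced until
now", so reversion is semantically impossible even if a learned CPT leaks
probability the other way).  A trajectory ends when the in-silico subject
dies or the time horizon is reached.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema_io import Node, PanelDataset
from .structure_learning import DBNModel

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedTrajectory",
    "SimulatedCohort",
    "simulate_followup",
    "simulate_population",
    "dequantize",
]


@dataclass
class SimulatedTrajectory:
    """One simulated follow-up: values per wave at offsets 0, 2, 4, ... years."""

    subject_id: str
    rep: int
    offsets: np.ndarray  # years
    values: np.ndarray  # (n_waves, n_columns) discrete levels
    columns: list[str]  # dynamic variables followed by survival
    terminal_status: str  # "died" | "horizon_reached"

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "offset_years", self.offsets)
        return df


@dataclass
class SimulatedCohort:
    """All repetitions of all subjects, as one long frame.

    ``frame`` columns: subject_id, rep, offset_years, one column per dynamic
    variable, survival, terminal_status (repeated on every wave row).
    """

    frame: pd.DataFrame
    n_reps: int
    horizon_years: float
    seed: int
    columns: list[str]


class _Sampler:
    """Pre-compiled CPT lookup tables for fast repeated simulation."""

    def __init__(self, model: DBNModel):
        cat = model.catalog
        self.cat = cat
        self.dyn = cat.dynamic_names
        self.statics = cat.static_names
        self.outcome_idx = [i for i, v in enumerate(self.dyn) if cat[v].is_outcome]
        self.nodes = cat.nodes()
        self.pos = {n: i for i, n in enumerate(self.nodes)}
        self.tsb_rule = cat.scheme[cat.time_name]
        self.surv_node = Node(cat.survival_name, "survival")
        # per sampled node: (state positions of parents, strides, cumulative table)
        self.compiled: dict[Node, tuple[list[int], list[int], np.ndarray]] = {}
        for node in [Node(v, "t") for v in self.dyn] + [self.surv_node]:
            cpt = model.cpts[node]
            strides = []
            acc = 1
            for card in reversed(cpt.parent_cards):
                strides.append(acc)
                acc *= card
            strides = list(reversed(strides))
            ppos = [self.pos[p] for p in cpt.parents]
            self.compiled[node] = (ppos, strides, np.cumsum(cpt.table, axis=1))

    def step(self, state: list[int], uniforms: np.ndarray) -> tuple[list[int], int]:
        """Sample all slice-t variables and survival given the state vector."""
        out = []
        for j, var in enumerate(self.dyn):
            node = Node(var, "t")
            ppos, strides, cum = self.compiled[node]
            row = 0
            for p, s in zip(ppos, strides):
                row += state[p] * s
            val = int(np.searchsorted(cum[row], uniforms[j], side="right"))
            out.append(val)
            state[self.pos[node]] = val  # survival may condition on slice t
        ppos, strides, cum = self.compiled[self.surv_node]
        row = 0
        for p, s in zip(ppos, strides):
            row += state[p] * s
        surv = int(np.searchsorted(cum[row], uniforms[len(self.dyn)], side="right"))
        return out, surv


def _check_baseline(model: DBNModel, baseline: dict) -> None:
    cat = model.catalog
    needed = cat.dynamic_names + cat.static_names + [cat.survival_name]
    missing = [v for v in needed if v not in baseline or pd.isna(baseline[v])]
    if missing:
        raise ValueError(f"incomplete baseline record; missing {missing}")


def simulate_followup(model: DBNModel, baseline: dict, horizon_years: float,
                      rng: np.random.Generator, subject_id: str = "subject",
                      rep: int = 0, _sampler: _Sampler | None = None) -> SimulatedTrajectory:
    """Simulate one follow-up from a complete baseline record.

    ``baseline`` maps variable name -> discrete level for every dynamic and
    static variable plus survival.  The trajectory records the baseline wave
    and every simulated wave, stopping at death (survival = yes) or once the
    next step would pass the horizon.
    """
    _check_baseline(model, baseline)
    sampler = _sampler or _Sampler(model)
    cat = model.catalog
    dyn, statics = sampler.dyn, sampler.statics
    n_dyn = len(dyn)

    state = [0] * len(sampler.nodes)
    for v in statics:
        state[sampler.pos[Node(v, "static")]] = int(baseline[v])
    cur = [int(baseline[v]) for v in dyn]
    surv = int(baseline[cat.survival_name])

    offsets = [0.0]
    records = [cur + [surv]]
    status = "horizon_reached"
    if surv == 1:
        status = "died"
    else:
        offset = 0.0
        while offset + 2.0 <= horizon_years:
            offset += 2.0
            for j, v in enumerate(dyn):
                state[sampler.pos[Node(v, "t-1")]] = cur[j]
            state[sampler.pos[Node(cat.time_name, "time")]] = sampler.tsb_rule.level(offset)
            uniforms = rng.random(n_dyn + 1)
            nxt, surv = sampler.step(state, uniforms)
            for j in sampler.outcome_idx:
                if cur[j] == 1:
                    nxt[j] = 1  # absorbing clamp
            cur = nxt
            offsets.append(offset)
            records.append(cur + [surv])
            if surv == 1:
                status = "died"
                break
    return SimulatedTrajectory(
        subject_id, rep, np.asarray(offsets),
        np.asarray(records, dtype=np.int64), dyn + [cat.survival_name], status)


def simulate_population(model: DBNModel, baselines: PanelDataset | pd.DataFrame,
                        n_reps: int = 100, horizon_years: float = 12.0,
                        seed: int = 0) -> SimulatedCohort:
    """Simulate ``n_reps`` independent follow-ups per subject.

    ``baselines`` is a discrete panel (its first wave per subject is used)
    or a one-row-per-subject frame.  Each (subject, repetition) draws from
    its own counter-based substream of the master seed, so results do not
    depend on processing order.
    """
    if isinstance(baselines, PanelDataset):
        base = baselines.baseline()
    else:
        base = baselines
    sampler = _Sampler(model)
    cat = model.catalog
    cols = sampler.dyn + [cat.survival_name]

    blocks = []
    for si, (_, row) in enumerate(base.sort_values("subject_id").iterrows()):
        record = row.to_dict()
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(si, rep)))
            traj = simulate_followup(model, record, horizon_years, rng,
                                     subject_id=str(row["subject_id"]), rep=rep,
                                     _sampler=sampler)
            n = len(traj.offsets)
            blocks.append((np.repeat(traj.subject_id, n), np.repeat(rep, n),
                           traj.offsets, traj.values,
                           np.repeat(traj.terminal_status, n)))
    frame = pd.DataFrame({
        "subject_id": np.concatenate([b[0] for b in blocks]),
        "rep": np.concatenate([b[1] for b in blocks]),
        "offset_years": np.concatenate([b[2] for b in blocks]),
    })
    values = np.concatenate([b[3] for b in blocks], axis=0)
    for j, c in enumerate(cols):
        frame[c] = values[:, j]
    frame["terminal_status"] = np.concatenate([b[4] for b in blocks])
    return SimulatedCohort(frame, n_reps, horizon_years, seed, cols)


def dequantize(model: DBNModel, variable: str, level: int,
               rng: np.random.Generator) -> float:
    """Continuous value for a simulated discrete level.

    Drawn uniformly from the training pool of that (variable, level); if the
    pool is empty, falls back (with a warning) to a uniform draw over the
    level's interval truncated at the catalog bounds.  Either way the value
    discretises back to ``level``.
    """
    spec = model.catalog[variable]
    if not spec.is_quantized:
        raise ValueError(f"{variable} is not a quantised variable")
    rule = model.catalog.scheme[variable]
    if not (0 <= level < rule.n_levels):
        raise ValueError(f"level {level} out of range for {variable}")
    pool = model.level_pools.get((variable, level))
    if pool is not None and len(pool) > 0:
        return float(pool[int(rng.integers(len(pool)))])
    warnings.warn(f"empty training pool for {variable} level {level}; "
                  "drawing uniformly over the level interval")
    lo, hi = rule.interval(level, spec.bounds)
    return float(rng.uniform(lo, hi))
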