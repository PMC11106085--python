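"""Risk stratification by clustering simulated survival curves.

The learned DBN doubles as a simulator: subjects are grouped into cohorts by
the baseline levels of an outcome's parent variables, each cohort's onset
risk is summarised as a Kaplan-Meier curve over simulated follow-ups, the
curves are min-max normalised per time point and clustered with Ward's
criterion on Euclidean distances, and the number of risk groups is chosen by
majority vote over a panel of cluster validity indices on a 2-6 range.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .schema_io import Node, PanelDataset
from .simulation import simulate_population
from .structure_learning import DBNModel
from .evaluation import EventRecords, SurvivalCurve, extract_events, km_curve

logger = logging.getLogger(__name__)

__all__ = [
    "CohortKey",
    "StratifyConfig",
    "StratificationResult",
    "enumerate_cohorts",
    "cohort_km",
    "normalize_curves",
    "cluster_curves",
    "select_k",
    "stratify",
]


@dataclass(frozen=True)
class CohortKey:
    """A baseline parent-level combination, e.g. code "0001" over
    (BMI, fasting glucose, HbA1c, LDL)."""

    outcome: str
    parents: tuple[str, ...]
    code: str  # one digit per parent, catalog order

    def __post_init__(self) -> None:
        if len(self.code) != len(self.parents):
            raise ValueError("one code digit per parent required")

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.code)


def outcome_parents(model: DBNModel, outcome: str) -> list[str]:
    """Baseline stratification variables: the outcome's parents at slice t-1
    and static parents, excluding the outcome's own persistence loop,
    ordered as in the catalog."""
    child = Node(outcome, "t")
    parents = [p for p in model.dag.parents(child) if p.var != outcome and p.when != "time"]
    if not parents:
        raise ValueError(f"outcome {outcome!r} has no stratifiable parents")
    order = {name: i for i, name in enumerate(model.catalog.names)}
    return [p.var for p in sorted(parents, key=lambda p: order[p.var])]


def enumerate_cohorts(model: DBNModel, outcome: str, panel: PanelDataset
                      ) -> dict[CohortKey, list]:
    """Observed parent-level combinations at baseline, with member subjects.

    Uses every subject of the pooled panel with a complete baseline whose
    outcome has not yet occurred; combinations nobody exhibits are omitted.
    """
    parents = outcome_parents(model, outcome)
    base = panel.baseline()
    needed = [c for c in panel.variable_columns]
    base = base[base[needed].notna().all(axis=1)]
    base = base[base[outcome].astype(int) == 0]  # onset analysis: not prevalent
    cohorts: dict[CohortKey, list] = {}
    for _, row in base.iterrows():
        code = "".join(str(int(row[p])) for p in parents)
        key = CohortKey(outcome, tuple(parents), code)
        cohorts.setdefault(key, []).append(row["subject_id"])
    return dict(sorted(cohorts.items(), key=lambda kv: kv[0].code))


def cohort_km(model: DBNModel, panel: PanelDataset, members: list, outcome: str,
              n_reps: int = 100, horizon_years: float = 12.0,
              seed: int = 0) -> SurvivalCurve:
    """Simulated onset curve of one cohort (all repetitions pooled)."""
    base = panel.baseline()
    base = base[base["subject_id"].isin(members)]
    cohort = simulate_population(model, base, n_reps=n_reps,
                                 horizon_years=horizon_years, seed=seed)
    records = extract_events(cohort, outcome)
    if len(records) == 0 or not records.frame["event"].any():
        # no event anywhere: flat curve at 1
        frame = pd.DataFrame({"subject_id": base["subject_id"], "rep": 0,
                              "time": horizon_years, "event": False})
        return km_curve(EventRecords(frame, outcome))
    return km_curve(records)


def normalize_curves(curves: dict[CohortKey, SurvivalCurve],
                     grid: np.ndarray) -> pd.DataFrame:
    """Curve matrix on a common grid, min-max scaled per time point.

    Rows are cohorts; a time point where all curves agree maps to zero.
    The scaling is idempotent.
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    rows = {key.code: [c.at(t) for t in grid] for key, c in curves.items()}
    m = pd.DataFrame.from_dict(rows, orient="index", columns=[f"t{t:g}" for t in grid])
    lo, hi = m.min(axis=0), m.max(axis=0)
    span = hi - lo
    scaled = (m - lo).div(span.where(span > 0, 1.0), axis=1)
    scaled[span.index[span == 0]] = 0.0
    return scaled


def cluster_curves(matrix: pd.DataFrame) -> np.ndarray:
    """Ward-criterion agglomerative linkage on Euclidean distances."""
    if len(matrix) < 2:
        raise ValueError("need at least two rows")
    return linkage(matrix.to_numpy(), method="ward")


def _dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter."""
    ks = np.unique(labels)
    diam = max((dist[np.ix_(labels == k, labels == k)].max() for k in ks), default=0.0)
    inter = min((dist[np.ix_(labels == a, labels == b)].min()
                 for a, b in itertools.combinations(ks, 2)), default=np.inf)
    if diam == 0:
        return np.inf
    return inter / diam


def _c_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Hubert-Levin C-index: within-cluster distance sum positioned between
    the attainable extremes; smaller is better."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    within = labels[iu[0]] == labels[iu[1]]
    n_w = int(within.sum())
    if n_w == 0:
        return 0.0
    s = d[within].sum()
    d_sorted = np.sort(d)
    s_min, s_max = d_sorted[:n_w].sum(), d_sorted[-n_w:].sum()
    if s_max == s_min:
        return 0.0
    return float((s - s_min) / (s_max - s_min))


def select_k(matrix: pd.DataFrame, tree: np.ndarray,
             k_range: range = range(2, 7)) -> tuple[int, dict[str, int]]:
    """Majority vote over a validity-index panel.

    Indices: silhouette, Calinski-Harabasz and Dunn (maximised),
    Davies-Bouldin and C-index (minimised).  Each index votes for its best k
    in the range; the modal k wins, ties resolved toward the smallest k.  A
    range exceeding the number of cohorts is truncated with a warning.
    """
    n = len(matrix)
    ks = [k for k in k_range if k <= n]
    if len(ks) < len(list(k_range)):
        logger.warning("select_k: range truncated to %s for %d cohorts", ks, n)
    if not ks:
        raise ValueError("too few cohorts for any k in range")
    x = matrix.to_numpy()
    dist = squareform(pdist(x))
    index_funcs = {
        "silhouette": lambda: silhouette_score(x, labels),
        "calinski_harabasz": lambda: calinski_harabasz_score(x, labels),
        "davies_bouldin": lambda: -davies_bouldin_score(x, labels),
        "dunn": lambda: _dunn_index(dist, labels),
        "c_index": lambda: -_c_index(dist, labels),
    }
    scores: dict[str, dict[int, float]] = {name: {} for name in index_funcs}
    for k in ks:
        labels = fcluster(tree, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        for name, func in index_funcs.items():
            try:
                scores[name][k] = float(func())
            except ValueError:
                continue  # index undefined at this k (e.g. all singletons)
    votes: dict[str, int] = {}
    for name, per_k in scores.items():
        if per_k:
            best = max(sorted(per_k), key=lambda k: per_k[k])
            votes[name] = best
    if not votes:
        raise ValueError("no validity index produced a vote (degenerate curves)")
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.min()
    return int(top), votes


@dataclass
class StratifyConfig:
    n_reps: int = 100
    horizon_years: float = 12.0
    grid_step: float = 2.0
    min_cohort_size: int = 10
    k_range: range = field(default_factory=lambda: range(2, 7))
    seed: int = 0


@dataclass
class StratificationResult:
    outcome: str
    parents: tuple[str, ...]
    cohorts: dict[CohortKey, list]
    curves: dict[CohortKey, SurvivalCurve]
    matrix: pd.DataFrame
    linkage_tree: np.ndarray
    k: int
    labels: pd.Series  # cohort code -> cluster label
    votes: dict[str, int]
    small_cohorts: list[CohortKey]
    parent_level_profile: pd.DataFrame  # per cluster, distribution of parent levels
    degenerate: bool = False


def stratify(model: DBNModel, outcome: str, panel: PanelDataset,
             config: StratifyConfig | None = None) -> StratificationResult:
    """Full stratification analysis for one outcome.

    Cohorts below ``min_cohort_size`` are simulated but excluded from the
    clustering (their Kaplan-Meier curves are too noisy to compare).  The
    report includes, per cluster, the distribution of each parent's baseline
    level across member cohorts.
    """
    cfg = config or StratifyConfig()
    cohorts = enumerate_cohorts(model, outcome, panel)
    parents = next(iter(cohorts)).parents
    curves: dict[CohortKey, SurvivalCurve] = {}
    small: list[CohortKey] = []
    for i, (key, members) in enumerate(cohorts.items()):
        curves[key] = cohort_km(model, panel, members, outcome,
                                n_reps=cfg.n_reps, horizon_years=cfg.horizon_years,
                                seed=cfg.seed + i)
        if len(members) < cfg.min_cohort_size:
            small.append(key)
    clustered = {k: c for k, c in curves.items() if k not in small}
    grid = np.arange(cfg.grid_step, cfg.horizon_years + 1e-9, cfg.grid_step)
    matrix = normalize_curves(clustered, grid)
    tree = cluster_curves(matrix)
    degenerate = bool((matrix.to_numpy() == 0).all())
    if degenerate:
        logger.warning("stratify: all curves identical; cluster count is arbitrary")
        k, votes = min(cfg.k_range), {}
        labels = pd.Series(1, index=matrix.index)
    else:
        k, votes = select_k(matrix, tree, cfg.k_range)
        labels = pd.Series(fcluster(tree, k, criterion="maxclust"), index=matrix.index)

    rows = []
    for key in clustered:
        for pos, parent in enumerate(parents):
            rows.append({"cluster": int(labels[key.code]), "parent": parent,
                         "level": key.levels[pos],
                         "n_subjects": len(cohorts[key])})
    profile = (pd.DataFrame(rows)
               .groupby(["cluster", "parent", "level"])["n_subjects"].sum()
               .reset_index())
    return StratificationResult(outcome, parents, cohorts, curves, matrix, tree,
                                k, labels, votes, small, profile, degenerate)
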