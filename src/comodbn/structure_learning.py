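"""Layered two-slice discrete DBN learning.

The network is learned from transition instances (pairs of consecutive waves)
with a hybrid scheme: a conditional-independence skeleton restricts the
candidate parent sets, a greedy hill-climb under the layer matrix maximises
the BIC, and a subject-wise k-fold consensus (edges kept when present in at
least a fraction of the fold networks) provides the starting network for the
final search on the full training set.  Conditional probability tables are
posterior means under a symmetric Dirichlet prior (maximum a posteriori with
pseudo-counts).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .schema_io import (
    LayeredDAG,
    Node,
    PanelDataset,
    QuantizationRule,
    QuantizationScheme,
    VariableCatalog,
    WPDAG,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionTable",
    "CPT",
    "DBNModel",
    "LearnConfig",
    "build_transition_table",
    "bic_score",
    "ci_test",
    "learn_skeleton",
    "hill_climb",
    "cv_consensus",
    "fit_cpts",
    "learn_dbn",
]

MISSING = -1


@dataclass
class LearnConfig:
    """Knobs of the structure-learning pipeline.

    k_folds / retention_fraction control the consensus step (an edge must
    appear in at least ceil(retention_fraction * k_folds) fold networks);
    alpha is the significance level of the G^2 skeleton tests; pseudo_count
    is the symmetric Dirichlet prior of the CPT estimates; max_cond bounds
    the size of the conditioning sets tried in the skeleton phase.
    """

    k_folds: int = 50
    retention_fraction: float = 0.8
    alpha: float = 0.05
    pseudo_count: float = 1.0
    max_cond: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.retention_fraction <= 1):
            raise ValueError("retention_fraction must be in (0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


class TransitionTable:
    """Two-slice data layout: one instance per consecutive wave pair.

    Each instance holds the values of every slice-(t-1) node, the static
    nodes, TSB and survival at the later wave, and every slice-t node.
    Missing values (possible in outcome/survival columns only) are coded -1
    and excluded from any family that uses them.
    """

    def __init__(self, catalog: VariableCatalog, matrix: np.ndarray,
                 subject_ids: np.ndarray):
        self.catalog = catalog
        self.nodes: list[Node] = catalog.nodes()
        self._col = {n: i for i, n in enumerate(self.nodes)}
        self.matrix = matrix.astype(np.int64)
        self.subject_ids = subject_ids
        self.cards = np.array([catalog.node_cardinality(n) for n in self.nodes])
        self._family_cache: dict = {}
        self._ci_cache: dict = {}

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject_ids))

    def subset(self, keep_subjects) -> "TransitionTable":
        mask = np.isin(self.subject_ids, np.asarray(list(keep_subjects)))
        return TransitionTable(self.catalog, self.matrix[mask], self.subject_ids[mask])

    def column(self, node: Node) -> np.ndarray:
        return self.matrix[:, self._col[node]]

    def counts(self, nodes: list[Node]) -> tuple[np.ndarray, int]:
        """Joint count array over ``nodes`` (complete rows only) and the row count."""
        idx = [self._col[n] for n in nodes]
        sub = self.matrix[:, idx]
        ok = (sub >= 0).all(axis=1)
        sub = sub[ok]
        dims = tuple(int(self.cards[i]) for i in idx)
        if len(sub) == 0:
            return np.zeros(dims), 0
        flat = np.ravel_multi_index(tuple(sub.T), dims)
        counts = np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims)
        return counts.astype(float), len(sub)

    def family_bic(self, child: Node, parents: tuple[Node, ...]) -> float:
        """BIC contribution of one family: max log-likelihood minus
        (1/2) * (r_child - 1) * q_parents * ln(N)."""
        key = (child, tuple(sorted(parents, key=str)))
        hit = self._family_cache.get(key)
        if hit is not None:
            return hit
        counts, n = self.counts([*key[1], child])
        r = int(self.cards[self._col[child]])
        table = counts.reshape(-1, r)
        row_tot = table.sum(axis=1)
        nz = table > 0
        ll = float((table[nz] * np.log(table[nz])).sum()
                   - (row_tot[row_tot > 0] * np.log(row_tot[row_tot > 0])).sum())
        q = table.shape[0]
        penalty = 0.5 * (r - 1) * q * math.log(n) if n > 0 else 0.0
        score = ll - penalty
        self._family_cache[key] = score
        return score


def build_transition_table(panel: PanelDataset) -> TransitionTable:
    """Lay a discrete panel out as transition instances.

    One instance per consecutive wave pair per subject (subjects with a
    single wave contribute nothing); static variables are repeated; survival
    and TSB are taken at the later wave.
    """
    if panel.stage != "discrete":
        raise ValueError("transition table requires a discrete panel")
    cat = panel.catalog
    df = panel.data.sort_values(["subject_id", "wave"]).reset_index(drop=True)
    same_subj = df["subject_id"].shift(-1) == df["subject_id"]
    consecutive = df["wave"].shift(-1) == df["wave"] + 1
    first = (same_subj & consecutive).to_numpy()
    prev = df[first].reset_index(drop=True)
    nxt = df.shift(-1)[first].reset_index(drop=True)

    dropped = panel.data.groupby("subject_id")["wave"].count()
    n_single = int((dropped < 2).sum())
    if n_single:
        logger.warning("%d subject(s) with <2 waves contribute no transitions", n_single)

    nodes = cat.nodes()
    cols = []
    for node in nodes:
        if node.when == "static":
            src = prev[node.var]
        elif node.when == "t-1":
            src = prev[node.var]
        else:  # t, survival, time: taken at the later wave
            src = nxt[node.var]
        cols.append(src.to_numpy(dtype="float64", na_value=np.nan))
    m = np.stack(cols, axis=1)
    m = np.where(np.isnan(m), MISSING, m).astype(np.int64)
    return TransitionTable(cat, m, prev["subject_id"].to_numpy())


def bic_score(dag: LayeredDAG, data: TransitionTable) -> float:
    """Decomposable BIC (natural log, larger is better) of a layered DAG."""
    total = 0.0
    for node in data.nodes:
        total += data.family_bic(node, tuple(dag.parents(node)))
    return total


def ci_test(x: Node, y: Node, cond: tuple[Node, ...], data: TransitionTable) -> tuple[float, float]:
    """G^2 likelihood-ratio test of X independent of Y given ``cond``.

    Returns (G2, p).  Degrees of freedom are (r_x - 1)(r_y - 1) per
    conditioning configuration, counting only configurations with a nonzero
    marginal count.
    """
    if x == y or x in cond or y in cond:
        raise ValueError("nodes of a CI test must be distinct")
    key = (x, y, tuple(sorted(cond, key=str)))
    hit = data._ci_cache.get(key)
    if hit is not None:
        return hit
    counts, _ = data.counts([*cond, x, y])
    rx, ry = counts.shape[-2], counts.shape[-1]
    tables = counts.reshape(-1, rx, ry)
    g2 = 0.0
    nonempty = 0
    for t in tables:
        n = t.sum()
        if n == 0:
            continue
        nonempty += 1
        rows = t.sum(axis=1, keepdims=True)
        colz = t.sum(axis=0, keepdims=True)
        expected = rows * colz / n
        nz = t > 0
        g2 += 2.0 * float((t[nz] * np.log(t[nz] / expected[nz])).sum())
    df = (rx - 1) * (ry - 1) * nonempty
    result = (0.0, 1.0) if df <= 0 else (g2, float(chi2.sf(g2, df)))
    data._ci_cache[key] = result
    return result


def _cond_subsets(pool: list[Node], max_size: int):
    for size in range(min(len(pool), max_size) + 1):
        yield from itertools.combinations(pool, size)


def learn_skeleton(data: TransitionTable, catalog: VariableCatalog,
                   alpha: float = 0.05, max_cond: int = 2) -> dict[Node, set[Node]]:
    """Candidate parent set per node, max-min parents-children style.

    Grow phase: among the layer-allowed candidates, repeatedly admit the one
    with the maximal minimum association (the minimum taken over conditioning
    subsets of the current set, up to ``max_cond`` nodes); a candidate whose
    weakest association is not significant at ``alpha`` is never admitted.
    Shrink phase: drop members that become independent of the target given a
    subset of the others.
    """
    skeleton: dict[Node, set[Node]] = {}
    for child in catalog.nodes():
        allowed = [p for p in catalog.nodes() if catalog.edge_allowed(p, child)]
        cpc: list[Node] = []
        if allowed:
            remaining = list(allowed)
            while remaining:
                best, best_stat = None, 0.0
                for cand in list(remaining):
                    # weakest association over conditioning subsets
                    min_stat, max_p = math.inf, 0.0
                    for s in _cond_subsets(cpc, max_cond):
                        g2, p = ci_test(cand, child, s, data)
                        if p > max_p:
                            max_p = p
                        if g2 < min_stat:
                            min_stat = g2
                        if max_p > alpha:
                            break
                    if max_p > alpha:
                        remaining.remove(cand)  # independent: never admitted
                    elif min_stat > best_stat:
                        best, best_stat = cand, min_stat
                if best is None:
                    break
                cpc.append(best)
                remaining.remove(best)
            # shrink
            for cand in list(cpc):
                others = [c for c in cpc if c != cand]
                for s in _cond_subsets(others, max_cond):
                    if not s:
                        continue
                    _, p = ci_test(cand, child, s, data)
                    if p > alpha:
                        cpc.remove(cand)
                        break
        skeleton[child] = set(cpc)
    return skeleton


def hill_climb(data: TransitionTable, catalog: VariableCatalog,
               skeleton: dict[Node, set[Node]], start: LayeredDAG) -> LayeredDAG:
    """Greedy BIC search over add/delete moves.

    Additions are restricted to skeleton-permitted, layer-permitted edges;
    deletions may remove any current edge.  Edge reversal is excluded: the
    layer matrix fixes every edge's direction.  Ties break lexicographically
    on (child, parent).  The returned graph is a local optimum.
    """
    start.validate()
    dag = start.copy()
    parents: dict[Node, set[Node]] = {n: set(dag.parents(n)) for n in dag.nodes}
    fam = {n: data.family_bic(n, tuple(parents[n])) for n in dag.nodes}

    candidates: list[tuple[Node, Node]] = []  # (child, parent)
    for child, cps in skeleton.items():
        for p in cps:
            if catalog.edge_allowed(p, child):
                candidates.append((child, p))
    for child in parents:  # start edges must be deletable even if off-skeleton
        for p in parents[child]:
            if (child, p) not in candidates:
                candidates.append((child, p))
    candidates.sort(key=lambda e: (str(e[0]), str(e[1])))

    while True:
        best_delta, best_move = 0.0, None
        for child, parent in candidates:
            cur = parents[child]
            new = cur - {parent} if parent in cur else cur | {parent}
            delta = data.family_bic(child, tuple(new)) - fam[child]
            if delta > best_delta + 1e-12:
                best_delta, best_move = delta, (child, parent)
        if best_move is None:
            return dag
        child, parent = best_move
        if parent in parents[child]:
            dag.remove_edge(parent, child)
            parents[child].discard(parent)
        else:
            dag.add_edge(parent, child)
            parents[child].add(parent)
        fam[child] = data.family_bic(child, tuple(parents[child]))


def cv_consensus(data: TransitionTable, catalog: VariableCatalog,
                 config: LearnConfig) -> tuple[WPDAG, LayeredDAG]:
    """Subject-wise k-fold consensus network.

    Each fold's network is learned on the other k-1 folds starting from the
    empty network; edge occurrence counts form the weighted consensus graph,
    thresholded at the retention fraction (any residual cycle is broken by
    dropping minimum-count edges).
    """
    subjects = np.unique(data.subject_ids)
    if config.k_folds > len(subjects):
        raise ValueError(f"k_folds={config.k_folds} exceeds subject count {len(subjects)}")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(subjects))
    folds = np.array_split(subjects[order], config.k_folds)

    wpdag = WPDAG(catalog, config.k_folds)
    for i, fold in enumerate(folds):
        keep = np.setdiff1d(subjects, fold)
        sub = data.subset(keep)
        skel = learn_skeleton(sub, catalog, config.alpha, config.max_cond)
        dag = hill_climb(sub, catalog, skel, LayeredDAG(catalog))
        wpdag.add_dag(dag)
        logger.debug("fold %d/%d: %d edges", i + 1, config.k_folds, len(dag))
    consensus = wpdag.threshold(config.retention_fraction)
    return wpdag, consensus


@dataclass
class CPT:
    """Conditional probability table of one node.

    ``table`` has one row per parent configuration (row-major in the order of
    ``parents``, i.e. the last parent varies fastest) and one column per child
    state.  A parentless node has a single-row table (its marginal).
    """

    child: Node
    parents: tuple[Node, ...]
    parent_cards: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        q = int(np.prod(self.parent_cards)) if self.parents else 1
        if self.table.shape[0] != q:
            raise ValueError(f"CPT for {self.child}: expected {q} rows")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT rows for {self.child} must sum to 1")

    def row_index(self, parent_values: dict[Node, int]) -> int:
        if not self.parents:
            return 0
        vals = tuple(parent_values[p] for p in self.parents)
        return int(np.ravel_multi_index(vals, self.parent_cards))

    def row(self, parent_values: dict[Node, int]) -> np.ndarray:
        return self.table[self.row_index(parent_values)]


def fit_cpts(dag: LayeredDAG, data: TransitionTable,
             pseudo_count: float = 1.0) -> dict[Node, CPT]:
    """Maximum a posteriori CPTs under a symmetric Dirichlet prior.

    Each row is (count + pseudo_count) / (row total + pseudo_count * r_child);
    an unobserved parent configuration yields the uniform vector.
    """
    cpts: dict[Node, CPT] = {}
    for child in data.nodes:
        parents = tuple(dag.parents(child))
        counts, _ = data.counts([*parents, child])
        r = data.cards[data._col[child]]
        table = counts.reshape(-1, int(r)) + pseudo_count
        table = table / table.sum(axis=1, keepdims=True)
        cards = tuple(int(data.cards[data._col[p]]) for p in parents)
        cpts[child] = CPT(child, parents, cards, table)
    return cpts


@dataclass
class DBNModel:
    """A learned (or ground-truth) two-slice DBN.

    Holds the layered DAG, one CPT per node (single-row for parentless
    nodes), the catalog and quantisation scheme, and per-(variable, level)
    pools of training continuous values used for de-quantisation.
    """

    dag: LayeredDAG
    cpts: dict[Node, CPT]
    catalog: VariableCatalog
    level_pools: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, cpt in self.cpts.items():
            if tuple(self.dag.parents(node)) != cpt.parents:
                raise ValueError(f"CPT parents of {node} disagree with the DAG")

    @property
    def scheme(self) -> QuantizationScheme:
        return self.catalog.scheme

    def marginal(self, node: Node) -> np.ndarray:
        cpt = self.cpts[node]
        if cpt.parents:
            raise ValueError(f"{node} is not parentless")
        return cpt.table[0]

    def validate(self) -> None:
        self.dag.validate()

    # -- JSON serialisation ------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "nodes": [str(n) for n in self.dag.nodes],
            "edges": [[str(p), str(c)] for p, c in
                      sorted(self.dag.edges, key=lambda e: (str(e[0]), str(e[1])))],
            "cpts": {
                str(n): {
                    "parents": [str(p) for p in c.parents],
                    "parent_cards": list(c.parent_cards),
                    "table": c.table.tolist(),
                }
                for n, c in sorted(self.cpts.items(), key=lambda kv: str(kv[0]))
            },
            "level_pools": {
                f"{var}|{level}": np.asarray(pool).tolist()
                for (var, level), pool in sorted(self.level_pools.items())
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path, catalog: VariableCatalog) -> "DBNModel":
        doc = json.loads(Path(path).read_text())
        dag = LayeredDAG(catalog, [(Node.parse(p), Node.parse(c)) for p, c in doc["edges"]])
        cpts = {}
        for name, c in doc["cpts"].items():
            node = Node.parse(name)
            cpts[node] = CPT(node, tuple(Node.parse(p) for p in c["parents"]),
                             tuple(c["parent_cards"]), np.asarray(c["table"], dtype=float))
        pools = {}
        for key, vals in doc.get("level_pools", {}).items():
            var, _, level = key.rpartition("|")
            pools[(var, int(level))] = np.asarray(vals, dtype=float)
        return cls(dag, cpts, catalog, pools)


def collect_level_pools(panel: PanelDataset) -> dict[tuple[str, int], np.ndarray]:
    """Per-(variable, level) pools of observed continuous values.

    Built from an imputed (complete, continuous-valued) panel; the pools feed
    de-quantisation of simulated discrete levels.
    """
    pools: dict[tuple[str, int], np.ndarray] = {}
    cat = panel.catalog
    for spec in cat:
        if not spec.is_quantized or spec.name not in panel.data.columns:
            continue
        vals = panel.data[spec.name].dropna().astype(float).to_numpy()
        levels = np.searchsorted(cat.scheme[spec.name].thresholds, vals, side="right")
        for lev in range(cat.cardinality(spec.name)):
            pools[(spec.name, lev)] = np.sort(vals[levels == lev])
    return pools


def learn_dbn(train: PanelDataset, config: LearnConfig,
              imputed: PanelDataset | None = None) -> DBNModel:
    """Full learning pipeline on a discrete training panel.

    Transition table -> k-fold consensus -> hill-climb on the full training
    data starting from the consensus network -> MAP CPTs.  When the
    pre-discretisation (imputed) panel is supplied, per-level continuous
    value pools are stored for de-quantisation.
    """
    data = build_transition_table(train)
    _, consensus = cv_consensus(data, train.catalog, config)
    skel = learn_skeleton(data, train.catalog, config.alpha, config.max_cond)
    final = hill_climb(data, train.catalog, skel, consensus)
    cpts = fit_cpts(final, data, config.pseudo_count)
    pools = collect_level_pools(imputed) if imputed is not None else {}
    return DBNModel(final, cpts, train.catalog, pools)
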