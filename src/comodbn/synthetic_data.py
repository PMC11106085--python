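"""Synthetic ELSA-shaped panel generation from a known ground-truth DBN.

The generator builds a layered two-slice DBN with known structure and CPTs
(the "ground truth"), samples complete subject trajectories from it by
ancestral sampling, decorates discrete levels with continuous values, and
finally re-imposes the study's design missingness (biomarkers collected only
every other wave) plus optional completely-at-random blanking.  Every
downstream stage of the pipeline — imputation, structure and parameter
recovery, simulation fidelity, calibration — is testable against this known
generator without access to the restricted panel study it emulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema_io import (
    LayeredDAG,
    Node,
    PanelDataset,
    QuantizationRule,
    QuantizationScheme,
    VariableCatalog,
    VariableSpec,
)
from .structure_learning import CPT, DBNModel

logger = logging.getLogger(__name__)

__all__ = [
    "MissingnessPattern",
    "scenario_catalog",
    "make_ground_truth_dbn",
    "sample_panel",
    "apply_missingness",
]

_YN = ("No", "Yes")
_OUTCOME_NAMES = ("Diabetes", "Hypertension", "Heart problems")
# Baseline prevalence of the three comorbidities in an ageing panel
# (roughly: diabetes rare, hypertension common, heart problems intermediate).
_OUTCOME_PREVALENCE = {"Diabetes": 0.07, "Hypertension": 0.35, "Heart problems": 0.15}
_STATIC_POOL = ("Sex", "Baseline age", "Education")

FIRST_WAVE = 2  # panels are emitted with original wave numbers starting here


@dataclass
class MissingnessPattern:
    """Design + MCAR missingness.

    ``biomarker_cadence`` blanks biomarker cells on every other wave (the
    4-yearly nurse-visit design); ``mcar_rates`` maps a variable category to
    a completely-at-random blanking probability.  Survival, outcomes, sex,
    baseline age and time-since-baseline are never blanked.
    """

    biomarker_cadence: bool = True
    mcar_rates: dict[str, float] = field(default_factory=lambda: {
        "socio-demographic": 0.02,
        "lifestyle": 0.05,
        "health-indicator": 0.05,
        "physical-measurement": 0.10,
        "biomarker": 0.05,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, rate in self.mcar_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"MCAR rate for {cat} must be in [0, 1]")


def scenario_catalog(n_dynamic: int = 10, n_static: int = 3) -> VariableCatalog:
    """A reduced ELSA-shaped catalog for synthetic scenarios.

    ``n_dynamic`` counts the dynamic variables including up to three binary
    absorbing outcomes; the remainder alternates continuous biomarkers
    (2-level, observed only every other wave once missingness is applied)
    and 3-level categorical lifestyle variables.  Statics are drawn from
    sex / baseline age / education, in that order.
    """
    if n_dynamic < 1:
        raise ValueError("need at least one dynamic variable")
    if not (0 <= n_static <= 3):
        raise ValueError("n_static must be between 0 and 3")
    # outcomes need at least two risk companions to have multiple parents
    n_outcomes = max(0, min(3, n_dynamic - 2))
    n_risk = n_dynamic - n_outcomes

    specs: list[VariableSpec] = []
    scheme = QuantizationScheme()
    for name in _STATIC_POOL[:n_static]:
        if name == "Sex":
            specs.append(VariableSpec("Sex", "socio-demographic", "static",
                                      "categorical", ("Male", "Female")))
        elif name == "Baseline age":
            specs.append(VariableSpec("Baseline age", "socio-demographic", "static",
                                      "continuous", unit="years", bounds=(41.0, 95.0)))
            scheme["Baseline age"] = QuantizationRule((55.0, 65.0), "tertiles")
        else:
            specs.append(VariableSpec(
                "Education", "socio-demographic", "static", "categorical",
                ("Less than high-school", "High-school graduate", "College or more"),
                static_layer=2))

    for i in range(n_risk):
        if i % 2 == 0:
            name = f"Biomarker {i // 2 + 1}"
            specs.append(VariableSpec(name, "biomarker", "dynamic", "continuous",
                                      unit="au", is_biomarker=True, bounds=(0.0, 2.0)))
            scheme[name] = QuantizationRule((1.0,), "clinical")
        else:
            name = f"Lifestyle {i // 2 + 1}"
            specs.append(VariableSpec(name, "lifestyle", "dynamic", "categorical",
                                      ("Low", "Mid", "High")))
    for name in _OUTCOME_NAMES[:n_outcomes]:
        specs.append(VariableSpec(name, "outcome", "dynamic", "categorical", _YN,
                                  is_outcome=True))
    specs.append(VariableSpec("TSB", "time", "dynamic", "continuous", unit="years",
                              bounds=(0.0, 11.0)))
    scheme["TSB"] = QuantizationRule((4.0, 8.0), "manual")
    specs.append(VariableSpec("Survival", "survival", "static", "categorical", _YN))
    return VariableCatalog(specs, scheme)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _effect_cpt(child_card: int, parents: tuple[Node, ...], parent_cards: tuple[int, ...],
                weights: np.ndarray, base: float) -> np.ndarray:
    """Ordered-logistic CPT: parent levels shift a latent score monotonically."""
    q = int(np.prod(parent_cards)) if parents else 1
    table = np.zeros((q, child_card))
    configs = np.indices(parent_cards).reshape(len(parents), -1).T if parents else np.zeros((1, 0), int)
    for row, cfg in enumerate(configs):
        s = base
        for w, lev, card in zip(weights, cfg, parent_cards):
            s += w * (lev / (card - 1) - 0.5)
        if child_card == 2:
            p1 = _sigmoid(s)
            table[row] = (1 - p1, p1)
        else:
            # cumulative logit with evenly spaced cut points
            cuts = np.linspace(-1.0, 1.0, child_card - 1)
            cum = _sigmoid(cuts - s)  # P(child <= k)
            probs = np.diff(np.concatenate(([0.0], cum, [1.0])))
            table[row] = probs
    return table


def make_ground_truth_dbn(n_dynamic: int = 10, n_static: int = 3,
                          max_parents: int = 3, seed: int = 0,
                          effect_strength: float = 1.5,
                          dominant_outcome_parent: bool = False) -> DBNModel:
    """Random layered ground-truth DBN with controlled effect sizes.

    Every dynamic variable gets a persistence self-loop X[t-1] -> X[t]; risk
    variables receive up to ``max_parents`` parents in total; each outcome is
    absorbing and depends on at least two risk variables at t-1; survival has
    at least two parents.  Non-absorbing CPT rows are generated by an
    ordered-logistic model whose weights have magnitude at least
    ``effect_strength`` (so rows sit away from indifference).  With
    ``dominant_outcome_parent`` the first risk parent of each outcome gets a
    much larger weight than the others — a two-regime scenario.
    """
    if n_dynamic < 1 or max_parents < 1:
        raise ValueError("n_dynamic and max_parents must be >= 1")
    catalog = scenario_catalog(n_dynamic, n_static)
    outcomes = [s.name for s in catalog if s.is_outcome]
    risks = [v for v in catalog.dynamic_names if v not in outcomes]
    if outcomes and max_parents < 3:
        raise ValueError("outcomes need a self-loop plus >=2 risk parents; "
                         "max_parents must be >= 3")
    if outcomes and len(risks) < 2:
        raise ValueError("need >=2 risk variables to give outcomes multiple parents")

    rng = np.random.default_rng(seed)
    dag = LayeredDAG(catalog)
    weights: dict[Node, dict[Node, float]] = {}
    bases: dict[Node, float] = {}

    def _w(lo=effect_strength, hi=None, sign=None):
        hi = hi or 2.0 * effect_strength
        mag = rng.uniform(lo, hi)
        if sign is None:
            sign = rng.choice([-1.0, 1.0])
        return sign * mag

    static_nodes = [Node(v, "static") for v in catalog.static_names]
    tsb = Node(catalog.time_name, "time")

    # risk variables: self-loop plus a few extra parents
    for var in risks:
        child = Node(var, "t")
        self_p = Node(var, "t-1")
        dag.add_edge(self_p, child)
        w = {self_p: rng.uniform(2.0, 3.0)}  # persistence
        pool = static_nodes + [Node(v, "t-1") for v in risks if v != var] + [tsb]
        n_extra = int(rng.integers(0, min(max_parents - 1, len(pool)) + 1))
        for p in rng.choice(len(pool), size=n_extra, replace=False):
            parent = pool[int(p)]
            dag.add_edge(parent, child)
            w[parent] = _w()
        weights[child] = w
        bases[child] = rng.uniform(-0.3, 0.3)

    # outcomes: absorbing self-loop plus >=2 risk parents with positive weights
    for var in outcomes:
        child = Node(var, "t")
        self_p = Node(var, "t-1")
        dag.add_edge(self_p, child)
        if dominant_outcome_parent:
            # a fuller parent set gives each risk regime a continuum of cohorts
            n_risk_par = min(3, len(risks))
        else:
            n_risk_par = int(rng.integers(2, min(max_parents - 1, len(risks)) + 1))
        chosen = rng.choice(len(risks), size=n_risk_par, replace=False)
        w = {self_p: 0.0}  # hazard rows condition on self = No; Yes rows absorb
        for rank, p in enumerate(sorted(int(i) for i in chosen)):
            parent = Node(risks[p], "t-1")
            dag.add_edge(parent, child)
            if dominant_outcome_parent:
                w[parent] = 4.0 if rank == 0 else 0.3
            else:
                w[parent] = _w(sign=1.0)
        weights[child] = w
        prev = _OUTCOME_PREVALENCE.get(var, 0.1)
        bases[child] = float(np.log(prev / (1 - prev)))  # per-step hazard scale
    # survival: at least two parents; death within 4 years of the current
    # interview depends on the current (slice t) status plus baseline age
    surv = Node(catalog.survival_name, "survival")
    surv_pool = ([Node("Baseline age", "static")] if "Baseline age" in catalog.static_names else [])
    surv_pool += [Node(v, "t") for v in (outcomes[:1] + risks[:2])]
    surv_pool += [tsb]
    n_surv = max(2, min(max_parents, len(surv_pool) - 1))
    w = {}
    for p in surv_pool[:n_surv]:
        dag.add_edge(p, surv)
        w[p] = _w(sign=1.0)
    weights[surv] = w
    bases[surv] = float(np.log(0.03 / 0.97))

    # CPTs
    cpts: dict[Node, CPT] = {}
    for node in catalog.nodes():
        parents = tuple(dag.parents(node))
        cards = tuple(catalog.node_cardinality(p) for p in parents)
        r = catalog.node_cardinality(node)
        if not parents:
            if node.when in ("static", "t-1"):
                table = _marginal_row(node, catalog, rng)
            else:
                table = np.full((1, r), 1.0 / r)
            cpts[node] = CPT(node, parents, cards, table)
            continue
        wvec = np.array([weights[node][p] for p in parents])
        table = _effect_cpt(r, parents, cards, wvec, bases[node])
        if node.when == "t" and node.var in outcomes:
            # absorbing: once the outcome is Yes it stays Yes
            self_idx = parents.index(Node(node.var, "t-1"))
            configs = np.indices(cards).reshape(len(parents), -1).T
            table[configs[:, self_idx] == 1] = (0.0, 1.0)
        cpts[node] = CPT(node, parents, cards, table)

    model = DBNModel(dag, cpts, catalog)
    model.validate()
    return model


def _marginal_row(node: Node, catalog: VariableCatalog, rng: np.random.Generator) -> np.ndarray:
    """Baseline marginal of a parentless static / slice t-1 node."""
    r = catalog.node_cardinality(node)
    name = node.var
    if name in _OUTCOME_PREVALENCE:
        p = _OUTCOME_PREVALENCE[name]
        return np.array([[1 - p, p]])
    if name == "Sex":
        return np.array([[0.45, 0.55]])
    if name == "Education":
        return np.array([[0.54, 0.16, 0.30]])
    if name == "Baseline age":
        return np.array([[0.34, 0.33, 0.33]])
    if name == catalog.survival_name:
        return np.array([[0.97, 0.03]])
    probs = rng.uniform(0.3, 0.7, size=r)
    return (probs / probs.sum())[None, :]


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, probs: np.ndarray) -> int:
    """Inverse-CDF draw (counter-based generator upstream keeps this portable)."""
    return int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))


def sample_panel(model: DBNModel, n_subjects: int, n_waves: int = 6,
                 seed: int = 0) -> PanelDataset:
    """Ancestral sampling of complete subject trajectories.

    Baseline values are drawn from the slice t-1 / static marginals; each
    later wave from the CPTs given the previous wave.  Survival is sampled
    every wave (at baseline, conditioning on the baseline values themselves);
    a subject whose survival turns Yes at wave w contributes no later waves.
    Outcomes are absorbing by construction.  Returned panel is stage="raw"
    with continuous decoration (uniform within the level interval, outer
    intervals truncated at the catalog bounds); the generating discrete
    levels ride along in ``panel.levels``.
    """
    if n_waves < 2:
        raise ValueError("n_waves must be >= 2")
    cat = model.catalog
    tsb_rule = cat.scheme[cat.time_name]
    surv_node = Node(cat.survival_name, "survival")
    dyn = cat.dynamic_names
    statics = cat.static_names

    rows: list[dict] = []
    for si in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(si,)))
        sid = f"S{si:06d}"
        static_vals = {v: _draw(rng, model.cpts[Node(v, "static")].table[0]) for v in statics}
        # baseline from slice t-1 marginals (root layer)
        prev = {v: _draw(rng, model.cpts[Node(v, "t-1")].table[0]) for v in dyn}
        state = {Node(v, "static"): lv for v, lv in static_vals.items()}

        for w in range(n_waves):
            offset = 2.0 * w
            tsb_level = tsb_rule.level(offset)
            state[Node(cat.time_name, "time")] = tsb_level
            for v in dyn:
                state[Node(v, "t-1")] = prev[v]
            if w == 0:
                cur = dict(prev)
            else:
                cur = {}
                for v in dyn:
                    cpt = model.cpts[Node(v, "t")]
                    cur[v] = _draw(rng, cpt.row(state))
                    if cat[v].is_outcome and prev[v] == 1:
                        cur[v] = 1  # absorbing
            for v in dyn:  # survival may condition on slice t
                state[Node(v, "t")] = cur[v]
            surv = _draw(rng, model.cpts[surv_node].row(state))
            rows.append({"subject_id": sid, "wave": FIRST_WAVE + w,
                         **static_vals, **cur, "Survival": surv,
                         "TSB": tsb_level})
            if surv == 1:
                break
            prev = cur

    levels = pd.DataFrame(rows)
    order = ["subject_id", "wave"] + [n for n in cat.names if n in levels.columns]
    levels = levels[order]

    # continuous / label decoration
    data = levels.copy()
    decorate_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1 << 20,)))
    for spec in cat:
        name = spec.name
        if name not in data.columns:
            continue
        if name == cat.time_name:
            data[name] = 2.0 * (data["wave"] - FIRST_WAVE)
            continue
        if spec.domain_kind == "categorical":
            data[name] = [spec.levels[int(v)] for v in data[name]]
        else:
            rule = cat.scheme[name]
            vals = []
            for lv in data[name]:
                lo, hi = rule.interval(int(lv), spec.bounds)
                vals.append(decorate_rng.uniform(lo, hi))
            if spec.domain_kind == "ordinal":
                vals = [float(round(v)) for v in vals]
                # keep discretise(decorated) == level after rounding
                vals = [v if rule.level(v) == lv else rule.interval(int(lv), spec.bounds)[0]
                        for v, lv in zip(vals, data[name])]
            data[name] = vals
    return PanelDataset(data, cat, stage="raw", levels=levels)


def apply_missingness(panel: PanelDataset, pattern: MissingnessPattern) -> PanelDataset:
    """Blank cells per the design cadence and the MCAR rates.

    Biomarkers are observed only on waves with even original index (the
    4-yearly collection); additional MCAR blanking applies per category.
    Outcomes, survival, sex, baseline age and time since baseline are never
    blanked.
    """
    cat = panel.catalog
    out = panel.data.copy()
    rng = np.random.default_rng(pattern.seed)
    protected = set(cat.outcome_names) | {cat.survival_name, cat.time_name, "Sex", "Baseline age"}
    for spec in cat:
        name = spec.name
        if name not in out.columns or name in protected:
            continue
        col = out[name]
        blank = np.zeros(len(out), dtype=bool)
        if pattern.biomarker_cadence and spec.is_biomarker:
            blank |= (out["wave"] % 2 == 1).to_numpy()
        rate = pattern.mcar_rates.get(spec.category, 0.0)
        if rate > 0:
            blank |= rng.random(len(out)) < rate
        if blank.any():
            col = col.where(~blank, other=np.nan)
            out[name] = col
    return PanelDataset(out, cat, stage="raw", levels=panel.levels)
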