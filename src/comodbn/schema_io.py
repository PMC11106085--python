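"""Domain types and I/O for longitudinal comorbidity panels and layered DBN graphs.

The package models an ageing panel (one interview "wave" roughly every two
years) with a discrete two-slice dynamic Bayesian network.  This module holds
the variable catalog (which variables exist, their domains, their layer in the
DBN), the quantisation scheme for continuous variables, the long-format panel
container, and the graph containers (layered DAG and the weighted consensus
graph), together with CSV / YAML / GraphML readers and writers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "VariableCatalog",
    "QuantizationRule",
    "QuantizationScheme",
    "PanelDataset",
    "Node",
    "LayeredDAG",
    "WPDAG",
    "ALLOWED_PARENT_LAYERS",
    "elsa_catalog",
    "load_panel",
    "write_panel",
    "load_catalog",
    "write_catalog",
    "export_dag",
    "import_dag",
]

MISSING_SENTINELS = ("", "NA")

# Variable categories used in the catalog.
CATEGORIES = (
    "socio-demographic",
    "lifestyle",
    "health-indicator",
    "physical-measurement",
    "biomarker",
    "time",
    "outcome",
    "survival",
)


class SchemaError(ValueError):
    """Structural problem in an on-disk artifact (missing columns, bad header)."""


@dataclass(frozen=True)
class VariableSpec:
    """One variable of the panel.

    ``domain_kind`` is ``categorical`` (unordered labels), ``ordinal``
    (integer scores, quantised but never interpolated) or ``continuous``
    (real-valued, quantised and interpolable).  ``static_layer`` places a
    static variable in DBN layer 1 (demographics) or 2 (schooling).
    ``bounds`` are plausible physical bounds used to truncate the unbounded
    outer quantisation intervals when de-quantising.
    """

    name: str
    category: str
    temporal_kind: str  # "static" | "dynamic"
    domain_kind: str  # "categorical" | "ordinal" | "continuous"
    levels: tuple[str, ...] | None = None  # categorical labels, in code order
    unit: str | None = None
    is_biomarker: bool = False
    is_outcome: bool = False
    static_layer: int = 1
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.temporal_kind not in ("static", "dynamic"):
            raise ValueError(f"bad temporal_kind for {self.name}")
        if self.domain_kind == "categorical" and not self.levels:
            raise ValueError(f"categorical variable {self.name} needs levels")
        if (self.is_outcome or self.category == "survival") and self.levels != ("No", "Yes"):
            raise ValueError(f"outcome/survival variable {self.name} must be binary No/Yes")

    @property
    def is_quantized(self) -> bool:
        return self.domain_kind in ("ordinal", "continuous")


@dataclass(frozen=True)
class QuantizationRule:
    """Ordered thresholds defining half-open intervals [a, b).

    A value v maps to level ``#{t : t <= v}``; i.e. thresholds belong to the
    upper interval.  ``criterion`` records how the cuts were chosen
    (clinical, tertiles or manual).
    """

    thresholds: tuple[float, ...]
    criterion: str = "manual"

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("at least one threshold required")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.thresholds) + 1

    def level(self, value: float) -> int:
        return int(np.searchsorted(self.thresholds, value, side="right"))

    def interval(self, level: int, bounds: tuple[float, float] | None = None) -> tuple[float, float]:
        """The [lo, hi) interval of ``level``, outer intervals clipped to ``bounds``."""
        edges = [-math.inf, *self.thresholds, math.inf]
        lo, hi = edges[level], edges[level + 1]
        if bounds is not None:
            lo, hi = max(lo, bounds[0]), min(hi, bounds[1])
        return lo, hi


class QuantizationScheme(dict):
    """Mapping variable name -> QuantizationRule."""

    def level(self, var: str, value: float) -> int:
        return self[var].level(value)


@dataclass(frozen=True)
class Node:
    """A DBN node: a variable at a given slice.

    ``when`` is one of ``t-1``, ``t``, ``static``, ``survival``, ``time``.
    Dynamic variables appear twice (slices t-1 and t); static variables,
    survival and the time-since-baseline node appear once.
    """

    var: str
    when: str

    def __str__(self) -> str:  # used as GraphML node id
        return f"{self.var}@{self.when}"

    @staticmethod
    def parse(text: str) -> "Node":
        var, _, when = text.rpartition("@")
        return Node(var, when)


# Children in layer L may take parents only from these layers.  Layers 1
# (demographics), 3 (slice t-1) and 6 (time) are root layers.  No intra-slice
# edges exist at slice t because layer 4 is not its own allowed parent.
ALLOWED_PARENT_LAYERS: Mapping[int, frozenset[int]] = {
    1: frozenset(),
    2: frozenset({1}),
    3: frozenset(),
    4: frozenset({1, 2, 3, 6}),
    5: frozenset({1, 2, 3, 4, 6}),
    6: frozenset(),
}


class VariableCatalog:
    """Ordered collection of VariableSpec plus the quantisation scheme.

    Provides the node set of the two-slice DBN and the layer of every node:
    demographics -> 1, schooling -> 2, dynamic at t-1 -> 3, dynamic at t -> 4,
    survival -> 5, time-since-baseline -> 6.
    """

    def __init__(self, specs: Sequence[VariableSpec], scheme: QuantizationScheme):
        self._specs = {s.name: s for s in specs}
        if len(self._specs) != len(specs):
            raise ValueError("duplicate variable names")
        self.scheme = scheme
        for s in specs:
            if s.is_quantized and s.name not in scheme:
                raise ValueError(f"quantised variable {s.name} lacks a quantisation rule")

    # -- basic access ------------------------------------------------------
    def __iter__(self) -> Iterable[VariableSpec]:
        return iter(self._specs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> VariableSpec:
        return self._specs[name]

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def variables(self, **filters) -> list[VariableSpec]:
        out = []
        for s in self:
            if all(getattr(s, k) == v for k, v in filters.items()):
                out.append(s)
        return out

    @property
    def dynamic_names(self) -> list[str]:
        return [s.name for s in self if s.temporal_kind == "dynamic" and s.category not in ("survival", "time")]

    @property
    def static_names(self) -> list[str]:
        return [s.name for s in self if s.temporal_kind == "static" and s.category not in ("survival", "time")]

    @property
    def outcome_names(self) -> list[str]:
        return [s.name for s in self if s.is_outcome]

    @property
    def biomarker_names(self) -> list[str]:
        return [s.name for s in self if s.is_biomarker]

    @property
    def survival_name(self) -> str:
        (s,) = [s.name for s in self if s.category == "survival"]
        return s

    @property
    def time_name(self) -> str:
        (s,) = [s.name for s in self if s.category == "time"]
        return s

    def cardinality(self, name: str) -> int:
        s = self[name]
        if s.domain_kind == "categorical":
            return len(s.levels)
        return self.scheme[name].n_levels

    # -- DBN node set and layering ----------------------------------------
    def nodes(self) -> list[Node]:
        out: list[Node] = []
        for name in self.static_names:
            out.append(Node(name, "static"))
        for name in self.dynamic_names:
            out.append(Node(name, "t-1"))
        for name in self.dynamic_names:
            out.append(Node(name, "t"))
        out.append(Node(self.survival_name, "survival"))
        out.append(Node(self.time_name, "time"))
        return out

    def layer_of(self, node: Node) -> int:
        if node.when == "static":
            return self[node.var].static_layer
        if node.when == "t-1":
            return 3
        if node.when == "t":
            return 4
        if node.when == "survival":
            return 5
        if node.when == "time":
            return 6
        raise ValueError(f"unknown slice {node.when!r}")

    def edge_allowed(self, parent: Node, child: Node) -> bool:
        return self.layer_of(parent) in ALLOWED_PARENT_LAYERS[self.layer_of(child)]

    def node_cardinality(self, node: Node) -> int:
        return self.cardinality(node.var)

    # -- value coding ------------------------------------------------------
    def code(self, name: str, value) -> int:
        """Integer level of a raw value."""
        s = self[name]
        if s.domain_kind == "categorical":
            try:
                return s.levels.index(str(value))
            except ValueError:
                raise ValueError(f"value {value!r} not in domain of {name}") from None
        return self.scheme[name].level(float(value))


# ---------------------------------------------------------------------------
# Packaged catalog: the ELSA-style variable set.
# ---------------------------------------------------------------------------

_YN = ("No", "Yes")


def elsa_catalog() -> VariableCatalog:
    """The packaged ELSA-style catalog.

    Static demographics (sex, baseline age) sit in layer 1 and education in
    layer 2.  Twenty dynamic variables (lifestyle, health indicators, physical
    measurements, blood biomarkers and the three absorbing comorbidity
    outcomes) occupy slices t-1 / t.  Survival ("will death occur within 4
    years of this interview?") and time-since-baseline complete the node set.
    Quantisation cuts follow common clinical thresholds (e.g. BMI 25 / 30),
    training tertiles for baseline age and manual cuts for skewed scores.
    """
    specs = [
        VariableSpec("Sex", "socio-demographic", "static", "categorical", ("Male", "Female")),
        VariableSpec("Baseline age", "socio-demographic", "static", "continuous", unit="years",
                     bounds=(41.0, 100.0)),
        VariableSpec("Education", "socio-demographic", "static", "categorical",
                     ("Less than high-school", "High-school graduate", "College or more"),
                     static_layer=2),
        VariableSpec("Marital status", "socio-demographic", "dynamic", "categorical",
                     ("Married or civil partner", "Separated, divorced or widowed", "Never married")),
        VariableSpec("Retirement", "socio-demographic", "dynamic", "categorical", _YN),
        VariableSpec("Physical activity", "lifestyle", "dynamic", "categorical",
                     ("Hardly ever or never", "1-3 per month or 1 per week", "More than 1 per week")),
        VariableSpec("Smoking", "lifestyle", "dynamic", "categorical", ("Never", "Past", "Current")),
        VariableSpec("Drinking", "lifestyle", "dynamic", "categorical", _YN),
        VariableSpec("Drink count", "lifestyle", "dynamic", "ordinal", unit="days", bounds=(0, 7)),
        VariableSpec("ADL", "health-indicator", "dynamic", "ordinal", unit="score", bounds=(0, 5)),
        VariableSpec("IADL", "health-indicator", "dynamic", "ordinal", unit="score", bounds=(0, 5)),
        VariableSpec("BMI", "physical-measurement", "dynamic", "continuous", unit="kg/m^2",
                     bounds=(15.0, 60.0)),
        VariableSpec("Systolic BP", "physical-measurement", "dynamic", "continuous", unit="mmHg",
                     bounds=(80.0, 220.0)),
        VariableSpec("Diastolic BP", "physical-measurement", "dynamic", "continuous", unit="mmHg",
                     bounds=(40.0, 130.0)),
        VariableSpec("Fasting glucose", "biomarker", "dynamic", "continuous", unit="mmol/l",
                     is_biomarker=True, bounds=(2.5, 20.0)),
        VariableSpec("HbA1c", "biomarker", "dynamic", "continuous", unit="%",
                     is_biomarker=True, bounds=(3.0, 15.0)),
        VariableSpec("Cholesterol", "biomarker", "dynamic", "continuous", unit="mmol/l",
                     is_biomarker=True, bounds=(2.0, 12.0)),
        VariableSpec("HDL", "biomarker", "dynamic", "continuous", unit="mmol/l",
                     is_biomarker=True, bounds=(0.4, 4.0)),
        VariableSpec("LDL", "biomarker", "dynamic", "continuous", unit="mmol/l",
                     is_biomarker=True, bounds=(0.5, 8.0)),
        VariableSpec("Triglycerides", "biomarker", "dynamic", "continuous", unit="mmol/l",
                     is_biomarker=True, bounds=(0.2, 12.0)),
        VariableSpec("Fibrinogen", "biomarker", "dynamic", "continuous", unit="g/l",
                     is_biomarker=True, bounds=(1.0, 10.0)),
        VariableSpec("CRP", "biomarker", "dynamic", "continuous", unit="mg/l",
                     is_biomarker=True, bounds=(0.0, 50.0)),
        VariableSpec("Ferritin", "biomarker", "dynamic", "continuous", unit="ng/ml",
                     is_biomarker=True, bounds=(5.0, 1500.0)),
        VariableSpec("TSB", "time", "dynamic", "continuous", unit="years", bounds=(0.0, 11.0)),
        VariableSpec("Diabetes", "outcome", "dynamic", "categorical", _YN, is_outcome=True),
        VariableSpec("Hypertension", "outcome", "dynamic", "categorical", _YN, is_outcome=True),
        VariableSpec("Heart problems", "outcome", "dynamic", "categorical", _YN, is_outcome=True),
        VariableSpec("Survival", "survival", "static", "categorical", _YN),
    ]
    scheme = QuantizationScheme({
        "Baseline age": QuantizationRule((55.0, 65.0), "tertiles"),
        "Drink count": QuantizationRule((3.0,), "manual"),
        "ADL": QuantizationRule((1.0,), "manual"),
        "IADL": QuantizationRule((1.0,), "manual"),
        "BMI": QuantizationRule((25.0, 30.0), "clinical"),
        "Systolic BP": QuantizationRule((120.0, 140.0), "clinical"),
        "Diastolic BP": QuantizationRule((60.0, 90.0), "clinical"),
        "Fasting glucose": QuantizationRule((5.6,), "clinical"),
        "HbA1c": QuantizationRule((6.5,), "clinical"),
        "Cholesterol": QuantizationRule((5.2,), "clinical"),
        "HDL": QuantizationRule((1.3,), "clinical"),
        "LDL": QuantizationRule((3.4,), "clinical"),
        "Triglycerides": QuantizationRule((1.7,), "clinical"),
        "Fibrinogen": QuantizationRule((4.0,), "clinical"),
        "CRP": QuantizationRule((1.0, 3.0), "clinical"),
        "Ferritin": QuantizationRule((200.0,), "clinical"),
        "TSB": QuantizationRule((4.0, 8.0), "manual"),
    })
    return VariableCatalog(specs, scheme)


# The survival variable is special-cased throughout: in the panel it is a
# per-wave column like the outcomes, but in the DBN it occupies its own layer.
# elsa_catalog marks it temporal_kind="static" only to keep it out of the
# t-1/t slices; PanelDataset still stores it per wave.


# ---------------------------------------------------------------------------
# Panel container and CSV I/O
# ---------------------------------------------------------------------------

ID_COLS = ("subject_id", "wave")
STAGES = ("raw", "imputed", "discrete")


@dataclass
class PanelDataset:
    """Long-format panel: one row per (subject, wave).

    ``wave`` is 0-based after alignment; the time offset in years is
    ``2 * wave``.  ``stage`` tracks the preprocessing state: ``raw`` (original
    values, missing allowed), ``imputed`` (complete outside outcome/survival
    columns) or ``discrete`` (all values are integer levels).
    ``levels`` optionally carries the generating discrete levels of a
    synthetic panel (one column per variable, aligned with ``data``).
    """

    data: pd.DataFrame
    catalog: VariableCatalog
    stage: str = "raw"
    levels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = [c for c in ID_COLS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"panel lacks mandatory columns {missing}")
        unknown = [c for c in self.data.columns if c not in ID_COLS and c not in self.catalog]
        if unknown:
            raise SchemaError(f"unknown columns {unknown}")

    @property
    def variable_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLS]

    @property
    def subjects(self) -> list:
        return list(self.data["subject_id"].unique())

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def subject_frame(self, subject_id) -> pd.DataFrame:
        return self.data[self.data["subject_id"] == subject_id]

    def baseline(self) -> pd.DataFrame:
        """One row per subject at their first (lowest-wave) record."""
        d = self.data.sort_values(list(ID_COLS))
        return d.groupby("subject_id", sort=False).first().reset_index()

    def copy(self, **changes) -> "PanelDataset":
        base = dict(data=self.data.copy(), catalog=self.catalog, stage=self.stage,
                    levels=None if self.levels is None else self.levels.copy())
        base.update(changes)
        return PanelDataset(**base)

    def equals(self, other: "PanelDataset") -> bool:
        if self.stage != other.stage:
            return False
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            x, y = a[c], b[c]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(x.astype(float), y.astype(float), equal_nan=True):
                    return False
            elif not (x.fillna("").astype(str) == y.fillna("").astype(str)).all():
                return False
        return True


def _check_value(spec: VariableSpec, value: str, stage: str, row: int, col: str):
    """Parse and validate one CSV cell; returns the typed value."""
    if stage == "discrete":
        try:
            code = int(float(value))
        except ValueError:
            raise ValueError(f"row {row}, column {col!r}: non-integer level {value!r}") from None
        return code
    if spec.domain_kind == "categorical":
        if value not in spec.levels:
            raise ValueError(f"row {row}, column {col!r}: value {value!r} not in domain")
        return value
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"row {row}, column {col!r}: cannot parse {value!r} as number") from None


def load_panel(path, catalog: VariableCatalog, stage: str = "raw") -> PanelDataset:
    """Read a panel CSV (UTF-8, comma, header in catalog names).

    Empty cells and "NA" are missing.  Unknown columns are rejected; values
    are checked against each variable's domain and errors name the offending
    row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ID_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    unknown = [c for c in df.columns if c not in ID_COLS and c not in catalog]
    if unknown:
        raise SchemaError(f"{path}: unknown columns {unknown}")

    out = pd.DataFrame()
    out["subject_id"] = df["subject_id"]
    try:
        out["wave"] = df["wave"].astype(int)
    except ValueError:
        raise ValueError(f"{path}: column 'wave' must be integer") from None

    for col in df.columns:
        if col in ID_COLS:
            continue
        spec = catalog[col]
        vals = []
        for i, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw in MISSING_SENTINELS:
                vals.append(np.nan)
            else:
                vals.append(_check_value(spec, raw, stage, i, col))
        if stage == "discrete" or spec.domain_kind != "categorical":
            out[col] = pd.array(vals, dtype="float64" if stage != "discrete" else "Float64")
            if stage == "discrete":
                out[col] = out[col].astype("Int64")
        else:
            out[col] = vals
    if stage == "discrete":
        for col in out.columns:
            if col in ID_COLS:
                continue
            card = catalog.cardinality(col)
            bad = out[col].dropna()
            if len(bad) and ((bad < 0) | (bad >= card)).any():
                raise ValueError(f"{path}: column {col!r} has levels outside 0..{card - 1}")
    return PanelDataset(out, catalog, stage=stage)


def write_panel(panel: PanelDataset, path) -> None:
    """Write a panel CSV with deterministic column order (catalog order).

    Missing cells are written empty; discrete panels contain only integer
    levels.  ``load_panel(write_panel(p)) == p``.
    """
    cols = list(ID_COLS) + [n for n in panel.catalog.names if n in panel.data.columns]
    df = panel.data[cols].copy()
    for c in df.columns:
        if c in ID_COLS:
            continue
        if panel.stage == "discrete":
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
        elif panel.catalog[c].domain_kind == "categorical":
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(v))
        else:
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Graph containers
# ---------------------------------------------------------------------------


class LayeredDAG:
    """Directed acyclic graph over the catalog's node set under the layer matrix."""

    def __init__(self, catalog: VariableCatalog, edges: Iterable[tuple[Node, Node]] = ()):
        self.catalog = catalog
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(catalog.nodes())
        for p, c in edges:
            self.add_edge(p, c)

    def add_edge(self, parent: Node, child: Node) -> None:
        if parent not in self.graph or child not in self.graph:
            raise ValueError(f"unknown node in edge {parent} -> {child}")
        if not self.catalog.edge_allowed(parent, child):
            raise ValueError(
                f"edge {parent} -> {child} violates the layer matrix "
                f"({self.catalog.layer_of(parent)} -> {self.catalog.layer_of(child)})")
        self.graph.add_edge(parent, child)

    def remove_edge(self, parent: Node, child: Node) -> None:
        self.graph.remove_edge(parent, child)

    def has_edge(self, parent: Node, child: Node) -> bool:
        return self.graph.has_edge(parent, child)

    @property
    def nodes(self) -> list[Node]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[Node, Node]]:
        return set(self.graph.edges)

    def parents(self, node: Node) -> list[Node]:
        return sorted(self.graph.predecessors(node), key=str)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("graph contains a cycle")
        for p, c in self.graph.edges:
            if not self.catalog.edge_allowed(p, c):
                raise ValueError(f"illegal edge {p} -> {c}")

    def copy(self) -> "LayeredDAG":
        return LayeredDAG(self.catalog, self.edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, LayeredDAG) and self.edges == other.edges

    def __len__(self) -> int:
        return self.graph.number_of_edges()


class WPDAG:
    """Weighted consensus graph: per-edge occurrence counts over CV folds."""

    def __init__(self, catalog: VariableCatalog, k_folds: int):
        self.catalog = catalog
        self.k_folds = int(k_folds)
        self.counts: dict[tuple[Node, Node], int] = {}

    def add_dag(self, dag: LayeredDAG) -> None:
        for e in dag.edges:
            self.counts[e] = self.counts.get(e, 0) + 1

    def threshold(self, fraction: float) -> LayeredDAG:
        """Edges present in at least ceil(fraction * k_folds) folds.

        If the retained set is (defensively) cyclic, the lowest-count edge of
        each remaining cycle is dropped until the graph is acyclic.
        """
        need = math.ceil(fraction * self.k_folds)
        kept = [e for e, c in self.counts.items() if c >= need]
        dag = LayeredDAG(self.catalog, kept)
        while not nx.is_directed_acyclic_graph(dag.graph):
            cycle = nx.find_cycle(dag.graph)
            worst = min(cycle, key=lambda e: self.counts[(e[0], e[1])])
            dag.remove_edge(worst[0], worst[1])
        return dag

    def __eq__(self, other) -> bool:
        return (isinstance(other, WPDAG) and self.k_folds == other.k_folds
                and self.counts == other.counts)


def export_dag(dag: LayeredDAG | WPDAG, path) -> None:
    """Write a graph as GraphML plus a JSON edge-list mirror (same stem, .json).

    Nodes carry variable / slice / layer annotations; WPDAG edges carry their
    fold occurrence count.
    """
    path = Path(path)
    catalog = dag.catalog
    g = nx.DiGraph()
    for node in catalog.nodes():
        g.add_node(str(node), variable=node.var, slice=node.when,
                   layer=catalog.layer_of(node))
    record: dict = {"kind": "dag", "edges": []}
    if isinstance(dag, WPDAG):
        record["kind"] = "wpdag"
        record["k_folds"] = dag.k_folds
        for (p, c), n in sorted(dag.counts.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
            g.add_edge(str(p), str(c), count=int(n))
            record["edges"].append({"parent": str(p), "child": str(c), "count": int(n)})
    else:
        for p, c in sorted(dag.edges, key=lambda e: (str(e[0]), str(e[1]))):
            g.add_edge(str(p), str(c))
            record["edges"].append({"parent": str(p), "child": str(c)})
    nx.write_graphml(g, path)
    path.with_suffix(".json").write_text(json.dumps(record, indent=1))


def import_dag(path, catalog: VariableCatalog) -> LayeredDAG | WPDAG:
    """Re-read a graph written by :func:`export_dag` (from the JSON mirror)."""
    record = json.loads(Path(path).with_suffix(".json").read_text())
    if record["kind"] == "wpdag":
        w = WPDAG(catalog, record["k_folds"])
        for e in record["edges"]:
            w.counts[(Node.parse(e["parent"]), Node.parse(e["child"]))] = e["count"]
        return w
    return LayeredDAG(catalog, [(Node.parse(e["parent"]), Node.parse(e["child"]))
                                for e in record["edges"]])


# ---------------------------------------------------------------------------
# Catalog YAML I/O
# ---------------------------------------------------------------------------


def write_catalog(catalog: VariableCatalog, path) -> None:
    doc = {"variables": [], "quantization": {}}
    for s in catalog:
        entry = {
            "name": s.name, "category": s.category, "temporal_kind": s.temporal_kind,
            "domain_kind": s.domain_kind,
        }
        if s.levels:
            entry["levels"] = list(s.levels)
        if s.unit:
            entry["unit"] = s.unit
        if s.is_biomarker:
            entry["is_biomarker"] = True
        if s.is_outcome:
            entry["is_outcome"] = True
        if s.static_layer != 1:
            entry["static_layer"] = s.static_layer
        if s.bounds:
            entry["bounds"] = list(s.bounds)
        doc["variables"].append(entry)
    for name, rule in catalog.scheme.items():
        doc["quantization"][name] = {"thresholds": list(rule.thresholds),
                                     "criterion": rule.criterion}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_catalog(path) -> VariableCatalog:
    doc = yaml.safe_load(Path(path).read_text())
    specs = []
    for e in doc["variables"]:
        specs.append(VariableSpec(
            name=e["name"], category=e["category"], temporal_kind=e["temporal_kind"],
            domain_kind=e["domain_kind"],
            levels=tuple(e["levels"]) if "levels" in e else None,
            unit=e.get("unit"), is_biomarker=e.get("is_biomarker", False),
            is_outcome=e.get("is_outcome", False), static_layer=e.get("static_layer", 1),
            bounds=tuple(e["bounds"]) if "bounds" in e else None,
        ))
    scheme = QuantizationScheme({
        name: QuantizationRule(tuple(q["thresholds"]), q.get("criterion", "manual"))
        for name, q in doc.get("quantization", {}).items()
    })
    return VariableCatalog(specs, scheme)
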