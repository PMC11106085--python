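"""Transition layout, BIC closed forms, G^2 tests, hill-climb vs brute force,
consensus thresholding and MAP CPT estimation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import comodbn as cb
from comodbn.schema_io import Node
from comodbn.structure_learning import (
    TransitionTable,
    bic_score,
    build_transition_table,
    ci_test,
    cv_consensus,
    fit_cpts,
    hill_climb,
    learn_skeleton,
)


@pytest.fixture(scope="module")
def tiny_cat():
    # nodes: Sex (static), Biomarker 1 (binary) and Lifestyle 1 (3-level)
    # at both slices, survival, TSB
    return cb.scenario_catalog(2, 1)


def _table(cat, columns: dict[Node, np.ndarray], n: int) -> TransitionTable:
    """Build a TransitionTable directly; unspecified nodes are constant 0."""
    nodes = cat.nodes()
    m = np.zeros((n, len(nodes)), dtype=np.int64)
    for i, node in enumerate(nodes):
        if node in columns:
            m[:, i] = columns[node]
    return TransitionTable(cat, m, np.arange(n))


class TestTransitionTable:
    def test_instance_count_identity(self, small_aligned):
        tt = build_transition_table(small_aligned)
        waves = small_aligned.data.groupby("subject_id")["wave"].count()
        assert len(tt) == int((waves - 1).clip(lower=0).sum())

    def test_three_waves_two_instances(self, small_aligned):
        counts = small_aligned.data.groupby("subject_id")["wave"].count()
        sid = counts[counts == 3].index[0]
        one = cb.PanelDataset(
            small_aligned.data[small_aligned.data["subject_id"] == sid],
            small_aligned.catalog, stage="discrete")
        assert len(build_transition_table(one)) == 2

    def test_static_repeated_across_instances(self, small_aligned):
        tt = build_transition_table(small_aligned)
        sex = tt.column(Node("Sex", "static"))
        for sid in np.unique(tt.subject_ids)[:20]:
            vals = sex[tt.subject_ids == sid]
            assert len(set(vals)) == 1


class TestBIC:
    def test_closed_form_all_one_level(self, tiny_cat):
        x = Node("Biomarker 1", "t-1")
        tt = _table(tiny_cat, {x: np.zeros(10, dtype=int)}, 10)
        assert tt.family_bic(x, ()) == pytest.approx(-0.5 * math.log(10))

    def test_closed_form_even_split(self, tiny_cat):
        x = Node("Biomarker 1", "t-1")
        tt = _table(tiny_cat, {x: np.r_[np.zeros(5, int), np.ones(5, int)]}, 10)
        expected = 10 * math.log(0.5) - 0.5 * math.log(10)
        assert tt.family_bic(x, ()) == pytest.approx(expected)

    def test_decomposability(self, tiny_cat):
        rng = np.random.default_rng(0)
        x, y = Node("Biomarker 1", "t-1"), Node("Lifestyle 1", "t-1")
        tt = _table(tiny_cat, {x: rng.integers(0, 2, 200),
                               y: rng.integers(0, 3, 200)}, 200)
        empty = cb.LayeredDAG(tiny_cat)
        total = bic_score(empty, tt)
        by_hand = sum(tt.family_bic(n, ()) for n in tt.nodes)
        assert total == pytest.approx(by_hand)


class TestCITest:
    def test_perfect_dependence_closed_form(self, tiny_cat):
        x, y = Node("Biomarker 1", "t-1"), Node("Biomarker 1", "t")
        vals = np.r_[np.zeros(50, int), np.ones(50, int)]
        tt = _table(tiny_cat, {x: vals, y: vals}, 100)
        g2, p = ci_test(x, y, (), tt)
        assert g2 == pytest.approx(200 * math.log(2))
        assert p < 1e-6

    def test_balanced_independent_table(self, tiny_cat):
        x, y = Node("Biomarker 1", "t-1"), Node("Biomarker 1", "t")
        xv = np.tile([0, 0, 1, 1], 25)
        yv = np.tile([0, 1, 0, 1], 25)
        g2, p = ci_test(x, y, (), _table(tiny_cat, {x: xv, y: yv}, 100))
        assert g2 == pytest.approx(0.0)
        assert p == 1.0

    def test_chain_conditional_independence_level(self, tiny_cat):
        """X -> Z -> Y: the test of X _||_ Y | Z holds its nominal level."""
        x, z, y = Node("Biomarker 1", "t-1"), Node("Lifestyle 1", "t-1"), Node("Biomarker 1", "t")
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            xv = rng.integers(0, 2, 5000)
            zv = (xv + (rng.random(5000) < 0.3)) % 3
            yv = ((zv > 0).astype(int) ^ (rng.random(5000) < 0.2)).astype(int)
            tt = _table(tiny_cat, {x: xv, z: zv, y: yv}, 5000)
            _, p = ci_test(x, y, (z,), tt)
            hits += p > 0.05
        assert hits >= 0.9 * n_seeds

    def test_distinct_nodes_required(self, tiny_cat):
        x = Node("Biomarker 1", "t-1")
        with pytest.raises(ValueError):
            ci_test(x, x, (), _table(tiny_cat, {}, 10))


class TestSkeleton:
    def test_independent_variables_empty_sets(self, tiny_cat):
        rng = np.random.default_rng(5)
        cols = {n: rng.integers(0, tiny_cat.node_cardinality(n), 4000)
                for n in tiny_cat.nodes()}
        skel = learn_skeleton(_table(tiny_cat, cols, 4000), tiny_cat, alpha=0.01)
        n_edges = sum(len(v) for v in skel.values())
        assert n_edges <= 2  # a couple of false positives are tolerated

    def test_deterministic_edge_found_and_layers_respected(self, tiny_cat):
        rng = np.random.default_rng(6)
        xv = rng.integers(0, 2, 4000)
        cols = {Node("Biomarker 1", "t-1"): xv, Node("Biomarker 1", "t"): xv}
        skel = learn_skeleton(_table(tiny_cat, cols, 4000), tiny_cat)
        assert Node("Biomarker 1", "t-1") in skel[Node("Biomarker 1", "t")]
        for child, parents in skel.items():
            for p in parents:
                assert tiny_cat.edge_allowed(p, child)
                assert not (child.when == "t" and p.when == "t")


def _enumerate_family_optimum(tt, cat):
    """Exhaustive per-family search: the global BIC optimum of a layered DAG
    decomposes into independent family optimisations."""
    best_edges = []
    best_score = 0.0
    for child in cat.nodes():
        allowed = [p for p in cat.nodes() if cat.edge_allowed(p, child)]
        best = None
        for k in range(len(allowed) + 1):
            for combo in itertools.combinations(allowed, k):
                s = tt.family_bic(child, combo)
                if best is None or s > best[0]:
                    best = (s, combo)
        best_score += best[0]
        best_edges.extend((p, child) for p in best[1])
    return best_score, set(best_edges)


@pytest.fixture(scope="module")
def learned_data():
    model = cb.make_ground_truth_dbn(2, 1, seed=8)
    panel = cb.sample_panel(model, 2500, 3, seed=9)
    tt = build_transition_table(cb.discretize(cb.align_waves(panel)))
    return model, tt


class TestHillClimb:
    def test_attains_brute_force_optimum(self, learned_data, tiny_cat):
        model, tt = learned_data
        full_skel = {c: {p for p in tiny_cat.nodes() if tiny_cat.edge_allowed(p, c)}
                     for c in tiny_cat.nodes()}
        dag = hill_climb(tt, tiny_cat, full_skel, cb.LayeredDAG(tiny_cat))
        best_score, _ = _enumerate_family_optimum(tt, tiny_cat)
        assert bic_score(dag, tt) == pytest.approx(best_score)

    def test_true_dag_is_local_optimum(self, learned_data, tiny_cat):
        model, tt = learned_data
        skel = {c: set(model.dag.parents(c)) for c in tiny_cat.nodes()}
        out = hill_climb(tt, tiny_cat, skel, model.dag.copy())
        assert bic_score(out, tt) >= bic_score(model.dag, tt)

    def test_empty_skeleton_no_additions(self, learned_data, tiny_cat):
        _, tt = learned_data
        start = cb.LayeredDAG(tiny_cat)
        out = hill_climb(tt, tiny_cat, {c: set() for c in tiny_cat.nodes()}, start)
        assert out.edges == set()

    def test_score_non_decreasing_local_optimum(self, learned_data, tiny_cat):
        _, tt = learned_data
        full_skel = {c: {p for p in tiny_cat.nodes() if tiny_cat.edge_allowed(p, c)}
                     for c in tiny_cat.nodes()}
        dag = hill_climb(tt, tiny_cat, full_skel, cb.LayeredDAG(tiny_cat))
        base = bic_score(dag, tt)
        # no single legal move improves the score
        for child in tiny_cat.nodes():
            for parent in full_skel[child]:
                trial = dag.copy()
                if trial.has_edge(parent, child):
                    trial.remove_edge(parent, child)
                else:
                    trial.add_edge(parent, child)
                assert bic_score(trial, tt) <= base + 1e-9


class TestConsensus:
    def test_threshold_arithmetic(self, tiny_cat):
        w = cb.WPDAG(tiny_cat, 50)
        e_in = (Node("Biomarker 1", "t-1"), Node("Biomarker 1", "t"))
        e_out = (Node("Lifestyle 1", "t-1"), Node("Biomarker 1", "t"))
        w.counts[e_in] = 40
        w.counts[e_out] = 39  # needs >= 40 at the 80% threshold
        kept = w.threshold(0.8)
        assert e_in in kept.edges
        assert e_out not in kept.edges

    def test_identical_folds_give_that_dag(self):
        model = cb.make_ground_truth_dbn(3, 1, seed=10)
        panel = cb.sample_panel(model, 600, 4, seed=11)
        tt = build_transition_table(cb.discretize(cb.align_waves(panel)))
        wpdag, consensus = cv_consensus(tt, model.catalog,
                                        cb.LearnConfig(k_folds=4, seed=12))
        union = {e for e, c in wpdag.counts.items()}
        assert consensus.edges <= union
        assert all(c <= 4 for c in wpdag.counts.values())

    def test_too_many_folds_raises(self, small_aligned):
        tt = build_transition_table(small_aligned)
        with pytest.raises(ValueError):
            cv_consensus(tt, small_aligned.catalog,
                         cb.LearnConfig(k_folds=10 ** 6, seed=0))


class TestCPTs:
    def test_map_closed_form(self, tiny_cat):
        x = Node("Biomarker 1", "t-1")
        vals = np.r_[np.ones(30, int), np.zeros(70, int)]
        tt = _table(tiny_cat, {x: vals}, 100)
        cpts = fit_cpts(cb.LayeredDAG(tiny_cat), tt, pseudo_count=1.0)
        assert cpts[x].table[0] == pytest.approx([71 / 102, 31 / 102])

    def test_unobserved_configuration_uniform(self, tiny_cat):
        x, y = Node("Biomarker 1", "t-1"), Node("Biomarker 1", "t")
        tt = _table(tiny_cat, {x: np.zeros(50, int), y: np.ones(50, int)}, 50)
        dag = cb.LayeredDAG(tiny_cat, [(x, y)])
        cpts = fit_cpts(dag, tt, pseudo_count=1.0)
        assert cpts[y].table[1] == pytest.approx([0.5, 0.5])  # x=1 never seen

    def test_rows_sum_to_one(self, small_aligned):
        tt = build_transition_table(small_aligned)
        skel = learn_skeleton(tt, small_aligned.catalog)
        dag = hill_climb(tt, small_aligned.catalog, skel,
                         cb.LayeredDAG(small_aligned.catalog))
        for cpt in fit_cpts(dag, tt).values():
            assert np.allclose(cpt.table.sum(axis=1), 1.0)


class TestModelIO:
    def test_json_round_trip(self, scenario_model, tmp_path):
        path = tmp_path / "m.json"
        scenario_model.to_json(path)
        back = cb.DBNModel.from_json(path, scenario_model.catalog)
        assert back.dag.edges == scenario_model.dag.edges
        for node in scenario_model.cpts:
            assert np.allclose(back.cpts[node].table, scenario_model.cpts[node].table)
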