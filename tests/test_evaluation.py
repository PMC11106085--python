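"""Survival machinery: event extraction, Kaplan-Meier, log-rank, risk scores,
time-dependent AU-ROC / AUC-PR against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

import comodbn as cb
from comodbn.evaluation import EventRecords, _classify


def _records(times, events, outcome="Diabetes"):
    return EventRecords(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(times))],
        "rep": 0, "time": list(times), "event": list(events)}), outcome)


class TestExtractEvents:
    def test_panel_first_onset_and_censoring(self, elsa_cat):
        df = pd.DataFrame({
            "subject_id": ["a"] * 3 + ["b"] * 3 + ["c"] * 2,
            "wave": [0, 1, 2, 0, 1, 2, 0, 1],
            "Diabetes": [0, 0, 1, 0, 0, 0, 1, 1],
        })
        panel = cb.PanelDataset(df, elsa_cat, stage="discrete")
        ev = cb.extract_events(panel, "Diabetes")
        f = ev.frame.set_index("subject_id")
        assert f.loc["a", "time"] == 4.0 and f.loc["a", "event"].item()
        assert f.loc["b", "time"] == 4.0 and not f.loc["b", "event"].item()
        assert "c" not in f.index and ev.n_prevalent_excluded == 1

    def test_missing_outcome_censors_earlier(self, elsa_cat):
        df = pd.DataFrame({
            "subject_id": ["a"] * 3, "wave": [0, 1, 2],
            "Survival": [0, 0, np.nan],
        })
        panel = cb.PanelDataset(df, elsa_cat, stage="discrete")
        ev = cb.extract_events(panel, "Survival")
        assert ev.frame["time"].iloc[0] == 2.0  # last observed survival value

    def test_unknown_outcome(self, elsa_cat):
        panel = cb.PanelDataset(pd.DataFrame({"subject_id": ["a"], "wave": [0]}),
                                elsa_cat, stage="discrete")
        with pytest.raises(KeyError):
            cb.extract_events(panel, "BMI")

    def test_cohort_event_at_four_years(self, chain_model):
        cohort = cb.simulate_population(chain_model, _baseline_frame(), n_reps=1,
                                        horizon_years=12.0, seed=0)
        ev = cb.extract_events(cohort, "Survival")
        assert not ev.frame["event"].any()  # survival CPT never fires
        assert (ev.frame["time"] == 12.0).all()


def _baseline_frame():
    return pd.DataFrame({"subject_id": ["x"], "Biomarker 1": [0], "Survival": [0]})


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at 2 and 4; censored at 4, 6, 6 (events precede censorings at 4)
        rec = _records([2, 4, 4, 6, 6], [True, True, False, False, False])
        curve = cb.km_curve(rec)
        assert curve.times.tolist() == [2.0, 4.0]
        assert curve.survival == pytest.approx([0.8, 0.6])

    def test_no_events_flat_one(self):
        curve = cb.km_curve(_records([5, 6, 7], [False] * 3))
        assert curve.times.size == 0
        assert curve.at(10.0) == 1.0

    def test_all_events_at_one_time(self):
        curve = cb.km_curve(_records([1] * 5, [True] * 5))
        assert curve.at(1.0) == 0.0

    def test_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 10, 50).astype(float)
        curve = cb.km_curve(_records(times, [True] * 50))
        for t in np.unique(times):
            assert curve.at(t) == pytest.approx((times > t).mean())

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.integers(1, 12, 80).astype(float)
        events = rng.random(80) < 0.6
        curve = cb.km_curve(_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(float(kmf.predict(t)))


class TestLogrank:
    def test_identical_groups(self):
        a = _records([2, 4, 6, 8], [True, True, False, True])
        stat, p = cb.logrank(a, a)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        """Two tiny groups: the O - E / V arithmetic is done longhand here."""
        a = _records([1, 3], [True, True])
        b = _records([2, 4], [True, False])
        o_minus_e = 0.0
        var = 0.0
        data = [(1.0, "a", True), (3.0, "a", True), (2.0, "b", True), (4.0, "b", False)]
        for t in sorted({d[0] for d in data if d[2]}):
            at_risk = [d for d in data if d[0] >= t]
            n = len(at_risk)
            n_a = sum(1 for d in at_risk if d[1] == "a")
            d_t = sum(1 for d in at_risk if d[0] == t and d[2])
            o_a = sum(1 for d in at_risk if d[0] == t and d[2] and d[1] == "a")
            e_a = d_t * n_a / n
            o_minus_e += o_a - e_a
            if n > 1:
                var += d_t * (n_a / n) * (1 - n_a / n) * (n - d_t) / (n - 1)
        expected_stat = o_minus_e**2 / var
        stat, _ = cb.logrank(a, b)
        assert stat == pytest.approx(expected_stat)

    def test_separated_supports_significant(self):
        rng = np.random.default_rng(0)
        a = _records(rng.uniform(0, 2, 200), [True] * 200)
        b = _records(rng.uniform(5, 8, 200), [True] * 200)
        _, p = cb.logrank(a, b)
        assert p < 0.001

    def test_no_events_flagged_p_one(self):
        a = _records([2, 4], [False, False])
        stat, p = cb.logrank(a, a)
        assert (stat, p) == (0.0, 1.0)


class TestRiskScore:
    def test_no_events_zero(self):
        assert cb.risk_score(_records([12] * 10, [False] * 10), 12) == 0.0

    def test_all_events_at_zero_one(self):
        assert cb.risk_score(_records([0] * 10, [True] * 10), 12) == 1.0

    def test_half_events_at_zero(self):
        rec = _records([0] * 5 + [12] * 5, [True] * 5 + [False] * 5)
        assert cb.risk_score(rec, 12) == pytest.approx(0.5)

    def test_repetition_order_invariant(self):
        times = [2.0, 8.0, 12.0, 4.0, 12.0]
        events = [True, True, False, True, False]
        base = cb.risk_score(_records(times, events), 12)
        perm = np.random.default_rng(1).permutation(5)
        shuffled = cb.risk_score(_records([times[i] for i in perm],
                                          [events[i] for i in perm]), 12)
        assert shuffled == base

    def test_censored_to_event_never_decreases(self):
        """Turning any censored repetition into an event (same time) adds risk."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            times = rng.uniform(0, 12, n)
            events = rng.random(n) < 0.5
            if events.all():
                continue
            base = cb.risk_score(_records(times, events), 12)
            idx = int(np.flatnonzero(~events)[0])
            flipped = events.copy()
            flipped[idx] = True
            more = cb.risk_score(_records(times, flipped), 12)
            assert more >= base - 1e-12


def _brute_force_auroc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _brute_force_aucpr(scores, labels):
    """Exhaustive threshold sweep; step integration sum (R_i - R_{i-1}) P_i."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels, dtype=float)[order]
    s = np.asarray(scores, dtype=float)[order]
    tp = np.cumsum(y)
    n_pos = y.sum()
    ap, prev_recall = 0.0, 0.0
    for i in range(len(y)):
        if i + 1 < len(y) and s[i + 1] == s[i]:
            continue  # ties share a threshold
        precision = tp[i] / (i + 1)
        recall = tp[i] / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestTimeDependentMetrics:
    def test_perfect_ranking(self):
        rec = _records([2, 2, 10, 10], [True, True, False, False])
        risks = pd.Series([0.9, 0.8, 0.1, 0.2], index=[f"s{i}" for i in range(4)])
        a, n_pos, n_tot = cb.td_auroc(risks, rec, 4.0)
        assert (a, n_pos, n_tot) == (1.0, 2, 4)
        pr, _, _ = cb.td_aucpr(risks, rec, 4.0)
        assert pr == 1.0

    def test_constant_risks_half(self):
        rec = _records([2, 2, 10, 10], [True, True, False, False])
        risks = pd.Series(0.5, index=[f"s{i}" for i in range(4)])
        a, _, _ = cb.td_auroc(risks, rec, 4.0)
        assert a == pytest.approx(0.5)

    def test_censored_before_t_excluded(self):
        rec = _records([2, 3, 10], [True, False, False])
        risks = pd.Series([0.9, 0.5, 0.1], index=["s0", "s1", "s2"])
        _, n_pos, n_tot = cb.td_auroc(risks, rec, 4.0)
        assert (n_pos, n_tot) == (1, 2)  # s1 censored before t drops out

    @pytest.mark.parametrize("seed", range(10))
    def test_auroc_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        times = rng.integers(1, 8, n).astype(float)
        events = rng.random(n) < 0.6
        risks = pd.Series(np.round(rng.random(n), 1), index=[f"s{i}" for i in range(n)])
        rec = _records(times, events)
        t = 4.0
        pos, kept = _classify(rec, t)
        if pos.sum() in (0, len(pos)):
            pytest.skip("degenerate draw")
        a, _, _ = cb.td_auroc(risks, rec, t)
        expected = _brute_force_auroc(
            risks.reindex(kept["subject_id"]).to_numpy(), pos.to_numpy())
        assert a == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_aucpr_matches_threshold_sweep(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 13))
        times = rng.integers(1, 8, n).astype(float)
        events = rng.random(n) < 0.6
        risks = pd.Series(np.round(rng.random(n), 1), index=[f"s{i}" for i in range(n)])
        rec = _records(times, events)
        pos, kept = _classify(rec, 4.0)
        if pos.sum() == 0:
            pytest.skip("degenerate draw")
        pr, _, _ = cb.td_aucpr(risks, rec, 4.0)
        expected = _brute_force_aucpr(
            risks.reindex(kept["subject_id"]).to_numpy(), pos.to_numpy())
        assert pr == pytest.approx(expected)

    def test_random_risks_aucpr_near_positive_rate(self):
        rng = np.random.default_rng(7)
        vals = []
        rate = None
        for _ in range(200):
            times = np.r_[np.full(40, 2.0), np.full(360, 10.0)]
            events = np.r_[np.ones(40, bool), np.zeros(360, bool)]
            risks = pd.Series(rng.random(400), index=[f"s{i}" for i in range(400)])
            rec = _records(times, events)
            pr, n_pos, n_tot = cb.td_aucpr(risks, rec, 4.0)
            vals.append(pr)
            rate = n_pos / n_tot
        assert abs(np.mean(vals) - rate) < 0.05


class TestIntegration:
    def test_integrated_auroc_published_series(self):
        assert cb.integrate_metric([0.808, 0.852, 0.833, 0.819]) == pytest.approx(0.828)

    def test_integrated_aucpr_published_series(self):
        assert cb.integrate_metric([0.253, 0.369]) == pytest.approx(0.311)

    def test_constant_series(self):
        assert cb.integrate_metric([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            cb.integrate_metric([float("nan")])


class TestEvaluateModel:
    def test_positive_rate_identity_and_bounds(self, scenario_model):
        panel = cb.sample_panel(scenario_model, 300, 6, seed=31)
        disc = cb.discretize(cb.align_waves(panel))
        res = cb.evaluate_model(scenario_model, disc,
                                cb.EvalConfig(n_reps=3, horizon_years=10.0, seed=32))
        for outcome, m in res.metrics.items():
            for rate, n_p, n_t in zip(m.positive_rate, m.n_positive, m.n_total):
                assert rate == pytest.approx(n_p / n_t)
            for v in m.auroc + m.aucpr:
                assert np.isnan(v) or 0.0 <= v <= 1.0
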