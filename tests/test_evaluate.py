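"""Staging agreement metrics: hand-arithmetic and published-value oracles."""

import numpy as np
import pytest

import polystage as ps
from polystage.evaluate import (accuracy, ahi_class, cohens_kappa, confusion,
                                estimate_tst, evaluate, f1_from_pr,
                                increase_rate, per_class_metrics,
                                second_choice_table, topk_accuracy,
                                weighted_metrics)

# Published clinical benchmark: per-stage precision/recall and predicted-epoch
# counts of a 150,103-epoch test set (W, N1, N2, N3, R).
BENCH_PRECISION = [0.8920, 0.6352, 0.8433, 0.6138, 0.8123]
BENCH_RECALL = [0.8680, 0.4667, 0.9059, 0.3919, 0.9171]
BENCH_COUNTS = [25_408, 17_992, 78_843, 2_100, 25_760]


class TestConfusion:
    def test_identical_sequences_diagonal(self):
        h = ps.Hypnogram(["W", "N1", "N2", "N3", "R", "N2"])
        cm = confusion(h, h)
        assert cm.sum() == 6
        assert (cm == np.diag(np.diag(cm))).all()

    def test_hand_count(self):
        cm = confusion(["W", "W", "R"], ["W", "R", "R"])
        assert cm[0, 0] == 1 and cm[0, 4] == 1 and cm[4, 4] == 1
        assert cm.sum() == 3

    def test_length_mismatch(self):
        with pytest.raises(Exception, match="mismatch"):
            confusion(["W"], ["W", "R"])


class TestF1:
    @pytest.mark.parametrize("p,r,expected", [
        (0.8920, 0.8680, 0.8799),     # W
        (0.6352, 0.4667, 0.5381),     # N1
        (0.6138, 0.3919, 0.4784),     # N3
        (0.8123, 0.9171, 0.8615),     # R
    ])
    def test_published_f1_values(self, p, r, expected):
        # published F1 was computed from unrounded precision/recall, so the
        # recomputation from the printed 4-d.p. values may differ by 1 ulp
        assert f1_from_pr(p, r) == pytest.approx(expected, abs=1e-4)

    def test_degenerate_cases(self):
        assert f1_from_pr(1.0, 1.0) == 1.0
        assert f1_from_pr(0.0, 0.0) == 0.0


class TestWeightedMetrics:
    def test_predicted_count_weighted_precision_reproduces_benchmark(self):
        assert round(weighted_metrics(BENCH_PRECISION, BENCH_COUNTS), 4) == 0.8181

    def test_single_class_passthrough(self):
        assert weighted_metrics([0.7], [123]) == pytest.approx(0.7)

    def test_uniform_values_invariant_to_weights(self):
        assert weighted_metrics([0.5] * 5, [1, 10, 100, 3, 7]) == pytest.approx(0.5)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_metrics([1.0], [0])

    def test_weighted_precision_identity_with_accuracy(self):
        """Σ TPᵢ/N == predicted-count-weighted precision, on any matrix."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            cm = rng.integers(0, 50, size=(5, 5))
            if cm.sum() == 0 or (cm.sum(axis=0) == 0).any():
                continue
            pc = per_class_metrics(cm)
            wp = weighted_metrics(pc["precision"].values, pc["predicted_count"].values)
            assert wp == pytest.approx(accuracy(cm), abs=1e-12)


class TestKappa:
    def test_diagonal_matrix_gives_one(self):
        cm = np.diag([10, 5, 20, 1, 8])
        assert cohens_kappa(cm) == pytest.approx(1.0)

    def test_two_class_hand_computation(self):
        cm = np.zeros((5, 5), int)
        cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = 45, 5, 15, 35
        # p_o = 0.8, p_e = 0.5 → κ = 0.6
        assert cohens_kappa(cm) == pytest.approx(0.6)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 5, size=100_000)
        p = rng.integers(0, 5, size=100_000)
        assert abs(cohens_kappa(confusion(t, p))) < 0.02

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        t = rng.integers(0, 5, size=500)
        p = np.where(rng.random(500) < 0.6, t, rng.integers(0, 5, size=500))
        assert cohens_kappa(confusion(t, p)) == pytest.approx(
            cohen_kappa_score(t, p), abs=1e-12)


class TestTopK:
    def test_k5_always_one(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(5), size=50)
        t = rng.integers(0, 5, size=50)
        assert topk_accuracy(t, probs, k=5) == 1.0

    def test_enumerated_example(self):
        probs = np.array([
            [0.4, 0.35, 0.1, 0.1, 0.05],   # top-2 {W, N1}
            [0.1, 0.1, 0.4, 0.3, 0.1],     # top-2 {N2, N3}
            [0.3, 0.1, 0.1, 0.1, 0.4],     # top-2 {R, W}
        ])
        t = [ps.STAGE_INDEX[s] for s in ("W", "N1", "R")]
        assert topk_accuracy(t, probs, k=2) == pytest.approx(2 / 3)

    def test_tie_break_fixed_stage_order(self):
        probs = np.array([[0.25, 0.25, 0.25, 0.25, 0.0]])
        from polystage.evaluate import topk_sets

        np.testing.assert_array_equal(topk_sets(probs, 2)[0], [0, 1])

    @pytest.mark.parametrize("n", [1000])
    def test_top2_never_below_top1(self, n):
        rng = np.random.default_rng(3)
        for _ in range(20):
            probs = rng.dirichlet(np.full(5, 0.4), size=n // 20)
            t = rng.integers(0, 5, size=n // 20)
            t1 = topk_accuracy(t, probs, 1)
            t2 = topk_accuracy(t, probs, 2)
            assert t2 >= t1
            assert topk_accuracy(t, probs, 3) >= t2


class TestIncreaseRate:
    @pytest.mark.parametrize("t1,t2,expected", [
        (0.8341, 0.9611, 0.1270),      # normal-AHI cohort
        (0.8088, 0.9619, 0.1531),      # severe-OSA cohort
    ])
    def test_published_rates(self, t1, t2, expected):
        assert round(increase_rate(t1, t2), 4) == expected

    def test_equal_inputs_zero(self):
        assert increase_rate(0.9, 0.9) == 0.0

    def test_inverted_inputs_rejected(self):
        with pytest.raises(ValueError):
            increase_rate(0.9, 0.8)


class TestSecondChoice:
    def test_single_runner_up_gives_100_percent_cell(self):
        probs = np.tile([0.5, 0.3, 0.1, 0.06, 0.04], (7, 1))
        counts, pct = second_choice_table(probs)
        assert counts.loc["W", "N1"] == 7
        assert pct.loc["W", "N1"] == pytest.approx(100.0)
        assert np.isnan(pct.loc["W", "W"])

    def test_percentages_use_predicted_class_denominator(self):
        """The published N1 row: 3994 of 17,992 N1-predicted epochs → 22.20%."""
        assert round(100 * 3994 / 17_992, 2) == 22.20
        assert round(100 * 6294 / 17_992, 2) == 34.98
        rng = np.random.default_rng(4)
        probs = rng.dirichlet(np.ones(5), size=400)
        counts, pct = second_choice_table(probs)
        for i, s in enumerate(ps.STAGES):
            row_total = counts.loc[s].sum()
            if row_total:
                got = np.nansum(pct.loc[s].values)
                assert got == pytest.approx(100.0, abs=1e-9)

    def test_row_counts_bounded_by_predicted_total(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(5), size=300)
        counts, _ = second_choice_table(probs)
        pred = probs.argmax(axis=1)
        for i, s in enumerate(ps.STAGES):
            assert counts.loc[s].sum() == (pred == i).sum()


class TestAhiAndTst:
    @pytest.mark.parametrize("ahi,expected", [
        (1.4, "normal"), (11.1, "mild"), (15.0, "moderate"),
        (23.7, "moderate"), (30.0, "severe"), (51.8, "severe"),
    ])
    def test_severity_thresholds(self, ahi, expected):
        assert ahi_class(ahi) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ahi_class(-0.1)

    def test_tst_all_wake_zero(self):
        assert estimate_tst(ps.Hypnogram(["W"] * 10)) == 0.0

    def test_tst_arithmetic(self):
        labels = ["N2"] * 820 + ["W"] * 100
        assert estimate_tst(ps.Hypnogram(labels, 30.0)) == pytest.approx(410.0)
        # adding wake leaves TST unchanged
        assert estimate_tst(ps.Hypnogram(labels + ["W"], 30.0)) == pytest.approx(410.0)


class TestReport:
    def test_report_pure_and_complete(self):
        rng = np.random.default_rng(6)
        t = rng.integers(0, 5, size=600)
        p = np.where(rng.random(600) < 0.7, t, rng.integers(0, 5, size=600))
        probs = rng.dirichlet(np.ones(5), size=600)
        probs[np.arange(600), p] += 2.0
        probs /= probs.sum(axis=1, keepdims=True)
        ahi = rng.uniform(0, 60, size=600)
        r1 = evaluate(t, p, probs, ahi)
        r2 = evaluate(t, p, probs, ahi)
        assert r1.to_dict() == r2.to_dict()
        assert r1.top2_acc >= r1.top1_acc
        assert r1.increase_rate == pytest.approx(r1.top2_acc - r1.top1_acc)
        assert set(r1.by_severity.index) <= set(("normal", "mild", "moderate", "severe"))
        assert r1.n_epochs == 600
        assert "accuracy" in r1.summary()
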