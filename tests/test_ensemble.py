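"""Probability fusion and the REM-continuity expert rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polystage as ps
from polystage.ensemble import ExpertRuleConfig, apply_expert_rules, integrate


class TestIntegrate:
    def test_hand_arithmetic_two_models(self):
        p = np.array([[0.6, 0.4, 0, 0, 0], [0.2, 0.8, 0, 0, 0]])
        out, low = integrate(p, ps.EnsembleWeights(np.ones(2)))
        np.testing.assert_allclose(out, [0.4, 0.6, 0, 0, 0], atol=1e-12)
        assert not low

    def test_single_unmasked_model_passthrough(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(5), size=5)
        mask = np.array([True, True, False, True, True])
        out, low = integrate(p, ps.EnsembleWeights(np.ones(5)), mask)
        np.testing.assert_allclose(out, p[2], atol=1e-12)
        assert not low

    def test_all_masked_falls_back_uniform_low_confidence(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(5), size=5)
        out, low = integrate(p, ps.EnsembleWeights(np.ones(5)), np.ones(5, bool))
        np.testing.assert_allclose(out, p.mean(axis=0), atol=1e-12)
        assert low

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ps.EnsembleWeights(np.array([1, -0.1, 1, 1, 1]))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            ps.EnsembleWeights(np.zeros(5))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(0, 30))
    def test_output_is_probability_vector(self, seed, mask_bits):
        """Fusion output is non-negative and sums to 1 ± 1e-9 for any
        normalized inputs, weights and mask pattern."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.full(5, 0.5), size=5)
        w = ps.EnsembleWeights(rng.uniform(0.1, 3.0, size=5))
        mask = np.array([(mask_bits >> i) & 1 for i in range(5)], bool)
        out, _ = integrate(p, w, mask)
        assert np.all(out >= 0)
        assert abs(out.sum() - 1.0) < 1e-9


def _oracle_literal(seq, lookahead):
    return ["R" if "R" in seq[i + 1 : i + 1 + lookahead] else seq[i]
            for i in range(len(seq))]


def _oracle_gap_fill(seq, lookahead):
    """Per-position scan: convert a non-R epoch iff the nearest R epochs on
    both sides enclose a gap of at most `lookahead` non-R epochs."""
    out = list(seq)
    for i, lab in enumerate(seq):
        if lab == "R":
            continue
        left = next((j for j in range(i - 1, -1, -1) if seq[j] == "R"), None)
        right = next((j for j in range(i + 1, len(seq)) if seq[j] == "R"), None)
        if left is not None and right is not None and (right - left - 1) <= lookahead:
            out[i] = "R"
    return out


class TestExpertRules:
    def test_no_rem_sequence_unchanged(self):
        seq = ["W", "N1", "N2", "N3", "N2", "W"]
        for mode in ("literal", "gap_fill"):
            assert apply_expert_rules(seq, ExpertRuleConfig(mode=mode)) == seq

    def test_gap_fill_short_gap_converted(self):
        assert apply_expert_rules(["R", "N1", "N1", "R"]) == ["R", "R", "R", "R"]

    def test_literal_lookahead_converts_preceding_epochs(self):
        out = apply_expert_rules(["N2", "N2", "R"],
                                 ExpertRuleConfig(mode="literal", lookahead_epochs=8))
        assert out == ["R", "R", "R"]

    def test_gap_fill_leaves_unbounded_runs(self):
        # run not enclosed by R on both sides stays
        assert apply_expert_rules(["N2", "N2", "R", "N2"]) == ["N2", "N2", "R", "N2"]
        # gap longer than lookahead stays
        seq = ["R"] + ["N2"] * 9 + ["R"]
        assert apply_expert_rules(seq, ExpertRuleConfig(lookahead_epochs=8)) == seq

    def test_brute_force_equivalence_all_short_sequences(self):
        """Exhaustive check against independent per-position oracles on all
        {W, N1, R} sequences of length ≤ 6 with lookahead 2 (non-R labels are
        interchangeable under the rule), plus the full alphabet at length 3."""
        alphabets = [("W", "N1", "R")] * 4
        for n in range(1, 7):
            for seq in itertools.product(("W", "N1", "R"), repeat=n):
                seq = list(seq)
                assert apply_expert_rules(
                    seq, ExpertRuleConfig(mode="literal", lookahead_epochs=2)
                ) == _oracle_literal(seq, 2)
                assert apply_expert_rules(
                    seq, ExpertRuleConfig(mode="gap_fill", lookahead_epochs=2)
                ) == _oracle_gap_fill(seq, 2)
        for seq in itertools.product(ps.STAGES, repeat=3):
            seq = list(seq)
            for mode, oracle in (("literal", _oracle_literal),
                                 ("gap_fill", _oracle_gap_fill)):
                assert apply_expert_rules(
                    seq, ExpertRuleConfig(mode=mode, lookahead_epochs=2)
                ) == oracle(seq, 2)

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.sampled_from(ps.STAGES), min_size=1, max_size=40),
           st.integers(1, 10))
    def test_gap_fill_idempotent_and_r_monotone(self, seq, lookahead):
        cfg = ExpertRuleConfig(mode="gap_fill", lookahead_epochs=lookahead)
        once = apply_expert_rules(seq, cfg)
        twice = apply_expert_rules(once, cfg)
        assert once == twice
        # only ever changes labels TO R; never away from R
        for before, after in zip(seq, once):
            assert after == before or after == "R"
        assert once.count("R") >= seq.count("R")

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.sampled_from(ps.STAGES), min_size=1, max_size=40))
    def test_literal_mode_r_monotone(self, seq):
        out = apply_expert_rules(seq, ExpertRuleConfig(mode="literal"))
        for before, after in zip(seq, out):
            assert after == before or after == "R"


@pytest.fixture(scope="module")
def oracle_models():
    """Five quickly trained models on a tiny three-record study."""
    from dataclasses import replace

    items = ps.make_synthetic_dataset(ps.SyntheticStudyConfig(
        n_records=3, epochs_per_record=60, seed=77,
        train_fraction=0.67, val_fraction=0.33))
    cfg = ps.PipelineConfig()
    cfg = replace(cfg, train=replace(cfg.train, max_epochs=3, seed=77),
                  network=ps.NetworkSpec(blocks=(
                      ps.BlockSpec("trans_block", 4, 7, 3),
                      ps.BlockSpec("trans_block", 6, 5, 3),
                      ps.BlockSpec("conv_block", 6, 5, 3),
                      ps.BlockSpec("trans_block", 8, 5, 3),
                  )))
    return ps.train_group_models(items, cfg), cfg


class TestScoreRecord:
    def test_output_length_and_determinism(self, oracle_models, small_record):
        ens, cfg = oracle_models
        rec, hyp = small_record
        s1 = ps.score_record(rec, ens.models, ens.groups, ens.weights,
                             cfg.preprocess, cfg.noise, cfg.rules)
        s2 = ps.score_record(rec, ens.models, ens.groups, ens.weights,
                             cfg.preprocess, cfg.noise, cfg.rules)
        assert len(s1.hypnogram) == len(hyp)
        assert s1.hypnogram.labels == s2.hypnogram.labels
        np.testing.assert_allclose(s1.probabilities, s2.probabilities, atol=1e-7)
        np.testing.assert_allclose(s1.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_corrupt_channel_silences_only_its_groups(self, oracle_models, small_record):
        """Flatlining one EEG channel masks that group (and the all-channel
        group) in the affected epochs; the other groups keep scoring."""
        ens, cfg = oracle_models
        rec, _ = small_record
        bad = ps.inject_falloff(rec, ps.FalloffEvent("EEG_C3A2", 5, 10, "flatline"))
        scored = ps.score_record(bad, ens.models, ens.groups, ens.weights,
                                 cfg.preprocess, cfg.noise, cfg.rules)
        assert scored.noise_mask.flags[5:15, 0].all()
        assert scored.noise_mask.flags[5:15, 4].all()
        assert not scored.noise_mask.flags[5:15, 1:4].any()
        assert not scored.low_confidence[5:15].any()

    def test_per_epoch_frame_export(self, oracle_models, small_record):
        ens, cfg = oracle_models
        rec, _ = small_record
        scored = ps.score_record(rec, ens.models, ens.groups, ens.weights,
                                 cfg.preprocess, cfg.noise, cfg.rules)
        df = scored.to_frame()
        assert len(df) == len(scored.hypnogram)
        assert {"p_W", "p_N1", "p_N2", "p_N3", "p_R", "top1", "top2"} <= set(df.columns)
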