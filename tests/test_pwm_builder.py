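"""Random sequence sampling, the one-hot design system, least squares and the
Boltzmann conversion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pwmforge as pf
from pwmforge.pwm_builder import (
    EnergyWeights,
    SequenceSample,
    build_design_matrix,
    energies_to_pwm,
    generate_sequences,
    rescale_weights,
    solve_weights,
)


class TestGenerateSequences:
    def test_counts_and_lengths(self):
        sample = generate_sequences(20, x_extra=50, seed=1)
        assert len(sample.sequences) == 4 * 20 + 50 == 130
        assert all(len(s) == 20 for s in sample.sequences)

    def test_deterministic_in_seed(self):
        assert generate_sequences(8, 20, seed=5).sequences == \
            generate_sequences(8, 20, seed=5).sequences
        assert generate_sequences(8, 20, seed=5).sequences != \
            generate_sequences(8, 20, seed=6).sequences

    def test_minimal_sample(self):
        assert len(generate_sequences(1, 0, seed=0).sequences) == 4

    def test_x_extra_cap(self):
        with pytest.raises(ValueError, match="capped"):
            generate_sequences(5, 100_001, seed=0)


class TestDesignMatrix:
    def test_row_layout_for_ac(self):
        sample = SequenceSample(sequences=["AC"], seed=0, x_extra=0)
        row = build_design_matrix(sample)[0]
        np.testing.assert_array_equal(row, [1, 0, 0, 0, 0, 1, 0, 0])

    def test_exhaustive_enumeration_column_sums(self):
        seqs = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        a = build_design_matrix(SequenceSample(sequences=seqs, seed=0, x_extra=0))
        np.testing.assert_array_equal(a.sum(axis=0), np.full(8, 4.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rows_sum_to_motif_length(self, seed):
        sample = generate_sequences(6, 10, seed=seed)
        a = build_design_matrix(sample)
        np.testing.assert_array_equal(a.sum(axis=1), np.full(len(sample.sequences), 6.0))


class TestSolveWeights:
    def test_recovers_fitted_values_when_consistent(self):
        rng = np.random.default_rng(0)
        sample = generate_sequences(10, 50, seed=3)
        a = build_design_matrix(sample)
        w_true = rng.normal(size=40)
        b = a @ w_true
        w = solve_weights(a, b)
        np.testing.assert_allclose(a @ w.vector, b, rtol=1e-8)

    def test_gauge_shift_leaves_pwm_identical(self):
        rng = np.random.default_rng(1)
        sample = generate_sequences(10, 50, seed=3)
        a = build_design_matrix(sample)
        w_true = rng.normal(size=(10, 4))
        shifts = rng.normal(size=(10, 1))
        b1 = a @ w_true.reshape(-1)
        b2 = a @ (w_true + shifts).reshape(-1)
        p1 = energies_to_pwm(solve_weights(a, b1)).probs
        p2 = energies_to_pwm(solve_weights(a, b2)).probs
        np.testing.assert_allclose(p2, p1, atol=1e-9)

    def test_solution_beats_random_perturbations(self):
        rng = np.random.default_rng(2)
        sample = generate_sequences(6, 20, seed=9)
        a = build_design_matrix(sample)
        b = rng.normal(size=a.shape[0])  # generic, not in the column space
        w = solve_weights(a, b)
        base_res = np.linalg.norm(a @ w.vector - b)
        for _ in range(1000):
            pert = w.vector + rng.normal(scale=0.01, size=w.vector.shape)
            assert np.linalg.norm(a @ pert - b) >= base_res - 1e-12

    def test_underdetermined_warns_but_solves(self, caplog):
        a = build_design_matrix(SequenceSample(sequences=["ACGT"], seed=0, x_extra=0))
        with caplog.at_level("WARNING"):
            w = solve_weights(a, np.array([1.0]))
        assert "underdetermined" in caplog.text
        assert np.isfinite(w.vector).all()


class TestRescaleWeights:
    def _weights(self):
        rng = np.random.default_rng(4)
        return EnergyWeights(matrix=rng.normal(size=(4, 4)))

    def test_exactly_linear_calibration_reproduced(self):
        w = self._weights()
        seqs = ["ACGT", "TTTT", "GGCC", "ATAT"]
        ref_score = w.sequence_score(seqs[0])
        # lnKd shifts exactly linear in predicted score: slope 2 / RT
        rt = pf.pwm_builder.R_GAS * 298.15
        calib = [(s, 2.0 * (w.sequence_score(s) - ref_score) / rt) for s in seqs]
        scaled = rescale_weights(w, calib)
        assert scaled.units == "kJ/mol"
        assert scaled.metadata["calibration_slope"] == pytest.approx(2.0, rel=1e-9)

    def test_rescale_then_convert_identity(self):
        # converting rescaled weights at beta = 1/RT equals converting the
        # unscaled weights at beta = slope/RT
        w = self._weights()
        rt = pf.pwm_builder.R_GAS * 298.15
        calib = [("ACGT", 0.0), ("TTTT", 1.3), ("GGCC", -0.4), ("ATAT", 0.9)]
        scaled = rescale_weights(w, calib)
        slope = scaled.metadata["calibration_slope"]
        p1 = energies_to_pwm(scaled, beta=None).probs
        p2 = energies_to_pwm(w, beta=slope / rt).probs
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_slope_positive_when_weaker_binders_score_higher(self):
        w = EnergyWeights(matrix=np.array([[0.0, 1.0, 2.0, 3.0]] * 4))
        calib = [("AAAA", 0.0), ("CCCC", 1.0), ("GGGG", 2.0), ("TTTT", 3.0)]
        scaled = rescale_weights(w, calib)
        assert scaled.metadata["calibration_slope"] > 0

    def test_degenerate_calibration_rejected(self):
        w = self._weights()
        with pytest.raises(ValueError, match="degenerate"):
            rescale_weights(w, [("ACGT", 0.0), ("ACGT", 1.0)])


class TestBoltzmannConversion:
    def test_equal_weights_give_uniform_column(self):
        pwm = energies_to_pwm(EnergyWeights(matrix=np.full((3, 4), 2.5)))
        np.testing.assert_allclose(pwm.probs, 0.25)

    def test_beta_zero_limit_uniform(self):
        rng = np.random.default_rng(5)
        pwm = energies_to_pwm(EnergyWeights(matrix=rng.normal(size=(5, 4))), beta=0.0)
        np.testing.assert_allclose(pwm.probs, 0.25)

    def test_hand_computed_column(self):
        # weights (-ln2, 0, 0, 0) at beta=1: p = (2,1,1,1)/5
        w = EnergyWeights(matrix=np.array([[-np.log(2.0), 0.0, 0.0, 0.0]]))
        pwm = energies_to_pwm(w, beta=1.0)
        np.testing.assert_allclose(pwm.probs[0], [0.4, 0.2, 0.2, 0.2], atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_columns_stochastic_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(4, 4))
        pwm = energies_to_pwm(EnergyWeights(matrix=m))
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-12)
        # decreasing one weight raises its probability, lowers the others
        m2 = m.copy()
        m2[1, 2] -= 0.7
        pwm2 = energies_to_pwm(EnergyWeights(matrix=m2))
        assert pwm2.probs[1, 2] > pwm.probs[1, 2]
        others = [i for i in range(4) if i != 2]
        assert (pwm2.probs[1, others] < pwm.probs[1, others]).all()


class TestBuildPwm:
    def test_reproducible_from_seed(self, trained_model, planted_tc):
        p1 = pf.build_pwm(planted_tc, trained_model, x_extra=20, seed=11)
        p2 = pf.build_pwm(planted_tc, trained_model, x_extra=20, seed=11)
        np.testing.assert_array_equal(p1.probs, p2.probs)

    def test_insensitive_to_x_extra(self, trained_model, planted_tc):
        p20 = pf.build_pwm(planted_tc, trained_model, x_extra=20, seed=11)
        p50 = pf.build_pwm(planted_tc, trained_model, x_extra=50, seed=11)
        assert np.abs(p20.probs - p50.probs).max() < 0.05

    def test_score_sample_matches_manual_calls(self, trained_model, planted_tc):
        sample = generate_sequences(10, 0, seed=13)
        sample.sequences = sample.sequences[:5]
        b = pf.score_sample(trained_model, planted_tc, sample)
        for k, seq in enumerate(sample.sequences):
            manual = pf.score_complex(
                trained_model, pf.thread_sequence(planted_tc, seq).structure
            ).value
            assert b[k] == pytest.approx(manual, rel=1e-12)

    def test_duplicate_sequences_score_identically(self, trained_model, planted_tc):
        sample = SequenceSample(
            sequences=["ACGTACGTAC", "ACGTACGTAC"], seed=0, x_extra=0
        )
        b = pf.score_sample(trained_model, planted_tc, sample)
        assert b[0] == b[1]

    def test_length_mismatch_rejected(self, trained_model, planted_tc):
        sample = generate_sequences(8, 0, seed=0)
        with pytest.raises(ValueError):
            pf.score_sample(trained_model, planted_tc, sample)
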