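import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erloc.pseaac import (DegenerateScaleError, FeatureParams,
                          SequenceTooShortError, WeightProfile, acc_factor,
                          assemble_feature, composition, covariance_vector,
                          featurize, standardize_scale, u_shape_weights,
                          weighted_profile)
from erloc.seqio import ALPHABET, ProteinSequence, one_hot_profile

sequences = st.text(alphabet=ALPHABET, min_size=2, max_size=80)


def scalar_weight_oracle(l, k):
    """Independent term-by-term evaluation of the U-shaped weight formula."""
    numer = [math.exp(k * (2 * j - l) / l) + math.exp(k * (l - 2 * j) / l)
             for j in range(1, l + 1)]
    total = sum(numer)
    return [l * n / total for n in numer]


def trace_oracle(S, u, v, lag):
    """Brute-force covariance factor via the explicit matrix-trace form."""
    l = S.length
    M = np.zeros((l, l))
    for i in range(1, l):
        M[i, i - 1] = 1.0  # shifting matrix: 1 on the first subdiagonal
    R = S.values @ np.outer(u.standardized, v.standardized) @ S.values.T
    return np.trace(R @ np.linalg.matrix_power(M, lag)) / (l - lag)


class TestUShapeWeights:
    def test_zero_k_gives_unit_weights(self):
        np.testing.assert_array_equal(u_shape_weights(3, 0.0).epsilon,
                                      np.ones(3))

    @pytest.mark.parametrize("l,k", [(5, 1.0), (17, 0.1), (40, 1.5)])
    def test_matches_scalar_oracle(self, l, k):
        np.testing.assert_allclose(u_shape_weights(l, k).epsilon,
                                   scalar_weight_oracle(l, k), atol=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(l=st.integers(2, 300), k=st.floats(0.0, 3.0))
    def test_conservation_and_symmetry(self, l, k):
        eps = u_shape_weights(l, k).epsilon
        assert abs(eps.sum() - l) < 1e-9
        assert (eps > 0).all()
        # discrete symmetry eps_j = eps_{l-j} for 1 <= j <= l-1 (1-based)
        head = eps[: l - 1]
        np.testing.assert_allclose(head, head[::-1], atol=1e-12)

    def test_terminal_transfer_monotone_in_k(self):
        ks = [0.0, 0.01, 0.1, 1.0, 1.5]
        l = 101
        terminal = [u_shape_weights(l, k).epsilon[-1] for k in ks]
        middle = [u_shape_weights(l, k).epsilon[l // 2] for k in ks]
        assert all(a <= b + 1e-15 for a, b in zip(terminal, terminal[1:]))
        assert all(a >= b - 1e-15 for a, b in zip(middle, middle[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            u_shape_weights(0, 1.0)
        with pytest.raises(ValueError):
            u_shape_weights(10, -0.1)


class TestStandardizeScale:
    def test_output_moments(self, rng):
        scale = standardize_scale("x", rng.normal(2, 3, size=20))
        assert scale.standardized.mean() == pytest.approx(0.0, abs=1e-9)
        assert (scale.standardized ** 2).mean() == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_idempotent_on_standardized_input(self, rng):
        once = standardize_scale("x", rng.normal(size=20)).standardized
        twice = standardize_scale("x", once).standardized
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            standardize_scale("flat", np.full(20, 3.3))


class TestWeightedProfile:
    def test_unit_weights_are_identity(self):
        prof = one_hot_profile(ProteinSequence("s", "GAKDEL"))
        S = weighted_profile(prof, u_shape_weights(6, 0.0))
        np.testing.assert_array_equal(S.values, prof.values)

    def test_row_sums_equal_epsilon(self, rng):
        seq = ProteinSequence("s", "".join(rng.choice(list(ALPHABET), 30)))
        weights = u_shape_weights(30, 1.2)
        S = weighted_profile(one_hot_profile(seq), weights)
        np.testing.assert_allclose(S.values.sum(axis=1), weights.epsilon,
                                   atol=1e-9)

    def test_explicit_scaled_entries(self):
        prof = one_hot_profile(ProteinSequence("s", "GA"))
        S = weighted_profile(prof, WeightProfile(np.array([2.0, 0.5]), 1.0))
        assert S.values[0, ALPHABET.index("G")] == 2.0
        assert S.values[1, ALPHABET.index("A")] == 0.5
        assert np.count_nonzero(S.values) == 2

    def test_length_mismatch(self):
        prof = one_hot_profile(ProteinSequence("s", "GA"))
        with pytest.raises(ValueError):
            weighted_profile(prof, u_shape_weights(3, 0.0))


class TestAccFactor:
    def test_two_residue_hand_value(self, scales):
        u, v = scales
        S = weighted_profile(one_hot_profile(ProteinSequence("s", "GA")),
                             u_shape_weights(2, 0.0))
        expected = u.standardized[ALPHABET.index("G")] \
            * v.standardized[ALPHABET.index("A")]
        assert acc_factor(S, u, v, 1) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("lag", [1, 3, 7])
    def test_homopolymer_constant_signal(self, scales, lag):
        u, v = scales
        S = weighted_profile(one_hot_profile(ProteinSequence("s", "A" * 12)),
                             u_shape_weights(12, 0.0))
        a = ALPHABET.index("A")
        expected = u.standardized[a] * v.standardized[a]
        assert acc_factor(S, u, v, lag) == pytest.approx(expected, abs=1e-9)

    def test_matches_trace_oracle_on_random_instances(self, scales, rng):
        u, v = scales
        for _ in range(100):
            l = int(rng.integers(5, 60))
            seq = ProteinSequence("s", "".join(rng.choice(list(ALPHABET), l)))
            S = weighted_profile(one_hot_profile(seq),
                                 u_shape_weights(l, float(rng.uniform(0, 2))))
            lag = int(rng.integers(1, l))
            su, sv = (u, v) if rng.uniform() < 0.5 else (v, u)
            direct = acc_factor(S, su, sv, lag)
            brute = trace_oracle(S, su, sv, lag)
            assert direct == pytest.approx(brute, rel=1e-9, abs=1e-12)

    def test_lag_exceeding_length(self, scales):
        u, v = scales
        S = weighted_profile(one_hot_profile(ProteinSequence("s", "GA")),
                             u_shape_weights(2, 0.0))
        with pytest.raises(SequenceTooShortError):
            acc_factor(S, u, v, 2)

    def test_cross_terms_are_asymmetric(self, scales):
        u, v = scales
        S = weighted_profile(one_hot_profile(ProteinSequence("s", "GAKW")),
                             u_shape_weights(4, 0.0))
        assert acc_factor(S, u, v, 1) != pytest.approx(acc_factor(S, v, u, 1))


class TestCovarianceVector:
    def test_lag_one_block_equals_acc_factors(self, scales):
        u, v = scales
        seq = ProteinSequence("s", "GAKDELWY")
        S = weighted_profile(one_hot_profile(seq), u_shape_weights(8, 0.5))
        V = covariance_vector(S, (u, v), 1)
        expected = [acc_factor(S, a, b, 1)
                    for a, b in ((u, u), (u, v), (v, u), (v, v))]
        np.testing.assert_allclose(V.flat, expected, atol=1e-12)

    def test_dimension_is_four_lambda(self, scales, rng):
        seq = ProteinSequence("s", "".join(rng.choice(list(ALPHABET), 30)))
        S = weighted_profile(one_hot_profile(seq), u_shape_weights(30, 0.1))
        assert covariance_vector(S, scales, 16).flat.shape == (64,)

    def test_scale_swap_permutes_blocks(self, scales, rng):
        u, v = scales
        seq = ProteinSequence("s", "".join(rng.choice(list(ALPHABET), 25)))
        S = weighted_profile(one_hot_profile(seq), u_shape_weights(25, 1.0))
        V = covariance_vector(S, (u, v), 5)
        W = covariance_vector(S, (v, u), 5)
        for lag in range(1, 6):
            b, c = V.block(lag), W.block(lag)
            np.testing.assert_allclose(c, [b[3], b[2], b[1], b[0]],
                                       atol=1e-12)

    def test_sequence_too_short(self, scales):
        S = weighted_profile(one_hot_profile(ProteinSequence("s", "GAKDE")),
                             u_shape_weights(5, 0.0))
        with pytest.raises(SequenceTooShortError):
            covariance_vector(S, scales, 5)


class TestComposition:
    def test_unweighted_two_residues(self):
        S = weighted_profile(one_hot_profile(ProteinSequence("s", "AC")),
                             u_shape_weights(2, 0.0))
        C = composition(S)
        assert C[ALPHABET.index("A")] == pytest.approx(0.5)
        assert C[ALPHABET.index("C")] == pytest.approx(0.5)
        assert C.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weighted_hand_value(self):
        eps = u_shape_weights(3, 1.0).epsilon
        S = weighted_profile(one_hot_profile(ProteinSequence("s", "AAC")),
                             u_shape_weights(3, 1.0))
        C = composition(S)
        assert C[ALPHABET.index("A")] == pytest.approx(
            (eps[0] + eps[1]) / 3, abs=1e-12)
        assert C[ALPHABET.index("C")] == pytest.approx(eps[2] / 3, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(sequences, st.floats(0.0, 2.5))
    def test_sums_to_one_and_nonnegative(self, residues, k):
        seq = ProteinSequence("s", residues)
        S = weighted_profile(one_hot_profile(seq),
                             u_shape_weights(seq.length, k))
        C = composition(S)
        assert C.sum() == pytest.approx(1.0, abs=1e-9)
        assert (C >= 0).all()


class TestFeatureAssembly:
    def test_omega_zero_reduces_to_composition(self, scales):
        seq = ProteinSequence("s", "GAKDELWYIVMN")
        params = FeatureParams(k=0.5, lam=3, omega=0.0)
        S = weighted_profile(one_hot_profile(seq),
                             u_shape_weights(seq.length, params.k))
        C = composition(S)
        V = covariance_vector(S, scales, params.lam)
        F = assemble_feature(C, V, 0.0, params)
        np.testing.assert_allclose(F.values[:20], C, atol=1e-12)
        np.testing.assert_array_equal(F.values[20:], 0.0)

    def test_dimension_at_lambda_sixteen(self, scales, rng):
        seq = ProteinSequence("s", "".join(rng.choice(list(ALPHABET), 40)))
        F = featurize(seq, one_hot_profile(seq), FeatureParams(), scales)
        assert F.values.shape == (84,)

    @settings(derandomize=True, max_examples=40)
    @given(residues=st.text(alphabet=ALPHABET, min_size=10, max_size=80),
           k=st.floats(0.0, 2.0), lam=st.integers(1, 8),
           omega=st.floats(0.0, 1.0))
    def test_entries_sum_to_one(self, scales, residues, k, lam, omega):
        seq = ProteinSequence("s", residues)
        params = FeatureParams(k=k, lam=lam, omega=omega)
        F = featurize(seq, one_hot_profile(seq), params, scales)
        assert F.values.sum() == pytest.approx(1.0, abs=1e-8)
        assert (F.values[:20] >= 0).all()

    def test_featurize_is_deterministic(self, scales):
        seq = ProteinSequence("s", "GAKDELWYIVMNPQRSTCFH")
        prof = one_hot_profile(seq)
        a = featurize(seq, prof, FeatureParams(), scales)
        b = featurize(seq, prof, FeatureParams(), scales)
        np.testing.assert_array_equal(a.values, b.values)

    def test_short_sequence_reports_id(self, scales):
        seq = ProteinSequence("tiny", "GAKDELWYIV")
        with pytest.raises(SequenceTooShortError, match="tiny"):
            featurize(seq, one_hot_profile(seq), FeatureParams(lam=16),
                      scales)


class TestTerminalEmphasis:
    def _distance(self, a, b, k, scales):
        params = FeatureParams(k=k, lam=4, omega=0.5)
        fa = featurize(a, one_hot_profile(a), params, scales).values
        fb = featurize(b, one_hot_profile(b), params, scales).values
        return float(np.linalg.norm(fa - fb))

    def test_terminal_difference_amplified_by_k(self, scales):
        base = "GAIVMNPQRSTCFHWYLEDK"
        a = ProteinSequence("a", base)
        b = ProteinSequence("b", "W" + base[1:-1] + "G")  # ends differ
        assert self._distance(a, b, 1.0, scales) \
            > self._distance(a, b, 0.0, scales)

    def test_central_difference_attenuated_by_k(self, scales):
        base = "GAIVMNPQRSTCFHWYLEDK"
        mid = len(base) // 2
        a = ProteinSequence("a", base)
        c = ProteinSequence("c", base[:mid] + "W" + base[mid + 1:])
        assert self._distance(a, c, 1.0, scales) \
            < self._distance(a, c, 0.0, scales)
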