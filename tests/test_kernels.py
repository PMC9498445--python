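import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mintruls as mt
from conftest import random_psd_kernel


def brute_force_profile_kernel(V, phi_prime=1.0):
    """Literal double-loop evaluation of the Gaussian profile kernel."""
    V = np.asarray(V, dtype=float)
    n = len(V)
    phi = phi_prime / (np.mean([v @ v for v in V]))
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = V[i] - V[j]
            K[i, j] = np.exp(-phi * (d @ d))
    return K


def nw_score_oracle(a, b, match=1.0, mismatch=-1.0, gap=-1.0):
    """Textbook global-alignment DP (independent of the biopython route)."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1))
    D[:, 0] = gap * np.arange(n + 1)
    D[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            D[i, j] = max(D[i - 1, j - 1] + s, D[i - 1, j] + gap,
                          D[i, j - 1] + gap)
    return D[n, m]


class TestGaussianProfileKernel:
    def test_identical_vectors_give_one(self):
        K = mt.gaussian_profile_kernel(np.ones((3, 4)))
        assert np.allclose(K.M, 1.0)

    def test_hand_evaluated_two_profiles(self):
        K = mt.gaussian_profile_kernel(np.array([[1., 0.], [0., 1.]]))
        assert K.M[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_doubling_phi_squares_offdiagonals(self, rng):
        V = rng.integers(0, 2, size=(6, 9)).astype(float)
        K1 = mt.gaussian_profile_kernel(V, phi_prime=1.0).M
        K2 = mt.gaussian_profile_kernel(V, phi_prime=2.0).M
        assert np.allclose(K2, K1**2, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for n, p in [(5, 3), (20, 11), (50, 17)]:
            V = rng.integers(0, 2, size=(n, p)).astype(float)
            if not V.any():
                continue
            K = mt.gaussian_profile_kernel(V).M
            assert np.abs(K - brute_force_profile_kernel(V)).max() < 1e-12

    def test_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            mt.gaussian_profile_kernel(np.zeros((3, 4)))


class TestScalarGaussianKernel:
    def test_equal_values_all_ones(self):
        K = mt.scalar_gaussian_kernel(np.array([-2., -2., -2.]))
        assert np.allclose(K.M, 1.0)

    def test_hand_evaluated_pair(self):
        K = mt.scalar_gaussian_kernel(np.array([1., 3.]))
        assert K.M[0, 1] == pytest.approx(np.exp(-0.8), abs=1e-12)

    def test_all_zero_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="unit bandwidth"):
            K = mt.scalar_gaussian_kernel(np.zeros(3))
        assert np.allclose(K.M, 1.0)


class TestNWKernel:
    def test_identical_sequences_unit_similarity(self):
        K = mt.nw_similarity_kernel(["AUGCAUGC", "AUGCAUGC"])
        assert K.M[0, 1] == 1.0

    def test_all_mismatch_clipped_to_zero(self):
        # s(AAAA, UUUU) = -4 (mismatches beat gapping), normalized -1 -> 0
        K = mt.nw_similarity_kernel(["AAAA", "UUUU"])
        assert K.M[0, 1] == 0.0

    def test_monotone_in_matches(self):
        K = mt.nw_similarity_kernel(["AUGC", "AUGC", "AUGG"])
        assert K.M[0, 1] > K.M[0, 2]

    def test_matches_dp_oracle_on_random_short_sequences(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=rng.integers(3, 7)))
                for _ in range(8)]
        K = mt.nw_similarity_kernel(seqs).M
        for i in range(len(seqs)):
            for j in range(len(seqs)):
                s = nw_score_oracle(seqs[i], seqs[j])
                expect = max(0.0, s / np.sqrt(len(seqs[i]) * len(seqs[j])))
                assert K[i, j] == pytest.approx(expect, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mt.nw_similarity_kernel(["AUGC", ""])


class TestIntegrateKernels:
    def make_kernels(self, rng, n=5, k=4):
        return [mt.SimilarityKernel([str(i) for i in range(n)],
                                    random_psd_kernel(rng, n))
                for _ in range(k)]

    def test_single_weight_returns_that_kernel(self, rng):
        ks = self.make_kernels(rng)
        out = mt.integrate_kernels(ks, (1, 0, 0, 0))
        assert np.array_equal(out.M, ks[0].M)

    def test_equal_weights_entrywise_mean(self, rng):
        ks = self.make_kernels(rng)
        out = mt.integrate_kernels(ks, (1, 1, 1, 1))
        assert np.allclose(out.M, np.mean([k.M for k in ks], axis=0))

    def test_hand_evaluated_cell(self):
        ids = ["a", "b"]
        vals = (0.2, 0.4, 0.6, 0.8)
        ks = [mt.SimilarityKernel(ids, np.array([[1.0, v], [v, 1.0]]))
              for v in vals]
        out = mt.integrate_kernels(ks, (2, 1, 1, 0))
        assert out.M[0, 1] == pytest.approx(0.35, abs=1e-12)

    def test_identical_kernels_fixed_point(self, rng):
        K = self.make_kernels(rng, k=1)[0]
        out = mt.integrate_kernels([K, K, K, K], (3, 1, 2, 5))
        assert np.allclose(out.M, K.M, atol=1e-12)

    def test_errors(self, rng):
        ks = self.make_kernels(rng)
        with pytest.raises(ValueError):
            mt.integrate_kernels(ks, (0, 0, 0, 0))
        other = mt.SimilarityKernel(["x"] * 0 + ["p", "q", "r", "s", "t"],
                                    random_psd_kernel(rng, 5))
        with pytest.raises(ValueError):
            mt.integrate_kernels([ks[0], ks[1], ks[2], other], (1, 1, 1, 1))


class TestNearestPSD:
    def test_psd_input_is_fixed_point(self, rng):
        M = random_psd_kernel(rng, 6)
        K = mt.SimilarityKernel([str(i) for i in range(6)], M)
        out = mt.nearest_psd(K)
        assert np.abs(out.M - M).max() < 1e-12

    def test_indefinite_2x2_projected(self):
        K = mt.SimilarityKernel(["a", "b"], np.array([[1.0, 1.2], [1.2, 1.0]]))
        out = mt.nearest_psd(K)
        vals = np.linalg.eigvalsh(out.M)
        assert vals.min() >= -1e-12
        assert np.allclose(np.diag(out.M), 1.0)

    def test_identity_unchanged(self):
        K = mt.SimilarityKernel(["a", "b", "c"], np.eye(3))
        assert np.array_equal(mt.nearest_psd(K).M, np.eye(3))


class TestKernelInvariants:
    """Symmetry, unit diagonal and range for every kernel builder."""

    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None)
    def test_builders_produce_valid_kernels(self, n, seed):
        rng = np.random.default_rng(seed)
        V = rng.integers(0, 2, size=(n, 7)).astype(float)
        builders = []
        if V.any():
            builders.append(mt.gaussian_profile_kernel(V))
        builders.append(mt.scalar_gaussian_kernel(rng.normal(size=n) - 5))
        seqs = ["".join(rng.choice(list("ACGU"), size=10)) for _ in range(n)]
        builders.append(mt.nw_similarity_kernel(seqs))
        for K in builders:
            K.validate()

    def test_permutation_equivariance(self, rng):
        V = rng.integers(0, 2, size=(7, 5)).astype(float)
        perm = rng.permutation(7)
        K = mt.gaussian_profile_kernel(V).M
        Kp = mt.gaussian_profile_kernel(V[perm]).M
        assert np.allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)
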