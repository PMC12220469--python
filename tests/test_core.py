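import numpy as np
import pytest

import iseq
from iseq.core import (damped_update, is_divergence, merge_sequences,
                       overlap_matrix, sequence_similarity, tensor_convolve,
                       _transpose_convolve, _update_W, EPS)


class TestTensorConvolve:
    def test_zero_intensity_gives_zero(self):
        W = np.random.default_rng(0).uniform(size=(3, 2, 4))
        assert (tensor_convolve(W, np.zeros((2, 13))) == 0).all()

    def test_degenerate_is_outer_product(self):
        w = np.array([1.0, 2.0, 3.0])
        h = np.array([[4.0, 5.0]])
        U = tensor_convolve(w.reshape(3, 1, 1), h)
        np.testing.assert_allclose(U, np.outer(w, h[0]))

    def test_impulse_stamps_pattern(self):
        # N=2, K=1, L=2; neuron 0 fires at lag 0, neuron 1 at lag 1
        W = np.zeros((2, 1, 2))
        W[0, 0, 0] = 1.0
        W[1, 0, 1] = 1.0
        T, L = 8, 2
        H = np.zeros((1, T + L - 1))
        H[0, 3 + (L - 1)] = 1.0         # impulse at recorded time 3
        U = tensor_convolve(W, H)
        expect = np.zeros((2, T))
        expect[0, 3] = 1.0
        expect[1, 4] = 1.0
        np.testing.assert_allclose(U, expect)

    def test_naive_triple_loop_agrees(self):
        rng = np.random.default_rng(1)
        N, K, L, T = 4, 3, 5, 12
        W = rng.uniform(size=(N, K, L))
        H = rng.uniform(size=(K, T + L - 1))
        U = tensor_convolve(W, H)
        naive = np.zeros((N, T))
        for n in range(N):
            for t in range(T):
                for k in range(K):
                    for l in range(L):
                        naive[n, t] += W[n, k, l] * H[k, t - l + L - 1]
        np.testing.assert_allclose(U, naive)


class TestISDivergence:
    def test_identity_is_zero(self, random_factors):
        V, _, _ = random_factors
        assert is_divergence(V, V) == pytest.approx(0.0)

    def test_scale_invariance(self, random_factors):
        V, W, H = random_factors
        U = tensor_convolve(W, H)
        for c in (0.1, 3.0, 250.0):
            assert is_divergence(c * V, c * U) == pytest.approx(
                is_divergence(V, U), rel=1e-9)

    def test_single_element_value(self):
        assert is_divergence([[2.0]], [[1.0]]) == pytest.approx(1 - np.log(2))

    def test_nonnegative(self, random_factors):
        V, W, H = random_factors
        assert is_divergence(V, tensor_convolve(W, H)) >= 0


class TestDampedUpdate:
    def test_monotone_over_200_iterations(self, random_factors):
        V, W, H = random_factors
        prev = np.inf
        for _ in range(200):
            W, H, D = damped_update(V, W, H)
            assert D <= prev + 1e-9
            prev = D
        assert (W >= 0).all() and (H >= 0).all()

    def test_fixed_point_when_reconstruction_exact(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(0.5, 1.0, size=(3, 1, 2))
        H = rng.uniform(0.5, 1.0, size=(1, 11))
        V = tensor_convolve(W, H)
        W2, H2, D = damped_update(V, W, H)
        assert D == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(tensor_convolve(W2, H2), V, rtol=1e-6)

    def test_halving_returns_point_on_segment(self):
        """When the raw step overshoots, the accepted factors are a
        midpoint-iterate between the old factors and the raw candidate."""
        rng = np.random.default_rng(3)
        V = rng.uniform(0.05, 1.0, (5, 30))
        W = rng.uniform(size=(5, 2, 3))
        H = rng.uniform(size=(2, 32))
        found = False
        for _ in range(300):
            U = tensor_convolve(W, H)
            Uc = np.maximum(U, EPS)
            A, B = V / Uc**2, 1.0 / Uc
            Wraw = _update_W(W, H, A, B, EPS)
            G = _transpose_convolve(W, np.stack([A, B]))
            Hraw = H * G[0] / np.maximum(G[1], EPS)
            D0 = is_divergence(V, U)
            W2, H2, D2 = damped_update(V, W, H)
            if is_divergence(V, tensor_convolve(Wraw, Hraw)) > D0:
                found = True
                # W2 = W + a (Wraw - W) with a = 2^-m shared by all entries
                num = (W2 - W).ravel()
                den = (Wraw - W).ravel()
                big = np.abs(den) > 1e-9
                a = num[big] / den[big]
                assert np.allclose(a, a[0])
                assert 0 < a[0] <= 1
                assert D2 <= D0 + 1e-9
            W, H = W2, H2
        assert found, "no overshooting step encountered"


class TestOverlap:
    def test_zero_slice_zero_row(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(size=(3, 2, 4))
        W[:, 1, :] = 0
        V = rng.uniform(size=(3, 20))
        R = overlap_matrix(W, V)
        assert (R[1] == 0).all() and (R[0] > 0).any()

    def test_peak_at_stamp_time(self):
        rng = np.random.default_rng(5)
        W = rng.uniform(size=(6, 1, 5))
        H = np.zeros((1, 40 + 4))
        H[0, 17 + 4] = 1.0
        V = tensor_convolve(W, H)
        R = overlap_matrix(W, V)
        assert np.argmax(R[0]) == 17

    def test_identical_slices_identical_rows(self):
        rng = np.random.default_rng(6)
        W = rng.uniform(size=(4, 2, 3))
        W[:, 1, :] = W[:, 0, :]
        V = rng.uniform(size=(4, 25))
        R = overlap_matrix(W, V)
        np.testing.assert_allclose(R[0], R[1])


class TestSimilarity:
    def test_identical_rows_full_similarity(self):
        r = np.sin(np.linspace(0, 20, 300))
        sim = sequence_similarity(np.vstack([r, r]), max_shift=5)
        assert sim[0, 1] == pytest.approx(1.0)

    def test_shifted_duplicate_similarity_one(self):
        rng = np.random.default_rng(7)
        r = rng.uniform(size=400)
        shifted = np.roll(r, 9)
        sim = sequence_similarity(np.vstack([r, shifted]), max_shift=20)
        assert sim[0, 1] > 0.999

    def test_independent_noise_low_similarity(self):
        rng = np.random.default_rng(8)
        R = rng.normal(size=(4, 3000))
        sim = sequence_similarity(R, max_shift=49)
        off = sim[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.3

    def test_constant_row_similarity_zero(self):
        R = np.vstack([np.ones(100), np.random.default_rng(9).uniform(size=100)])
        sim = sequence_similarity(R, max_shift=5)
        assert sim[0, 1] == 0.0
        assert sim[0, 0] == 1.0


class TestMerge:
    def _factors(self, K=3, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(size=(5, K, 3)), rng.uniform(size=(K, 22))

    def test_below_threshold_noop(self):
        W, H = self._factors()
        sim = np.eye(3) + 0.1
        W2, H2, keep = merge_sequences(W, H, sim, threshold=0.3)
        assert W2.shape[1] == 3 and keep == [0, 1, 2]

    def test_duplicate_reduces_k_by_one_keeping_higher_energy(self):
        W, H = self._factors()
        W[:, 1, :] = W[:, 0, :] * 2          # duplicate, higher energy
        H[1] = H[0] * 2
        sim = np.eye(3)
        sim[0, 1] = sim[1, 0] = 0.95
        W2, H2, keep = merge_sequences(W, H, sim, threshold=0.3)
        assert W2.shape[1] == 2
        assert keep == [1, 2]                # the low-energy copy was dropped

    def test_threshold_one_never_merges(self):
        W, H = self._factors()
        sim = np.ones((3, 3)) * 0.999
        np.fill_diagonal(sim, 1.0)
        W2, _, _ = merge_sequences(W, H, sim, threshold=1.0)
        assert W2.shape[1] == 3

    def test_sum_mode_accumulates_factors(self):
        W, H = self._factors()
        sim = np.eye(3)
        sim[0, 1] = sim[1, 0] = 0.9
        Wsum = W[:, 0, :] + W[:, 1, :]
        W2, H2, keep = merge_sequences(W, H, sim, threshold=0.3, mode="sum")
        assert W2.shape[1] == 2
        surv = keep[0]
        np.testing.assert_allclose(W2[:, 0, :], Wsum)


class TestFitSmall:
    def test_errors_on_short_recording(self):
        with pytest.raises(ValueError):
            iseq.fit(np.ones((3, 10)), L=20, restarts=1, iters=10)

    def test_scale_invariant_k_and_supports(self, small_synth):
        spec, clean, truth = small_synth
        V = clean.values[:, :600]
        kw = dict(L=spec.L, threshold=0.3, K0=6, restarts=1, iters=60, seed=2)
        d1 = iseq.fit(V, **kw)
        d2 = iseq.fit(5.0 * V, **kw)
        assert d1.n_sequences == d2.n_sequences
        np.testing.assert_allclose(d2.W.values, d1.W.values, rtol=1e-8, atol=1e-9)
        np.testing.assert_allclose(d2.H.values, 5.0 * d1.H.values, rtol=1e-8)

    def test_single_sequence_dataset_detected(self):
        spec = iseq.SyntheticSpec(K=1, N_s=40, T=1200, L=30, seed=21)
        clean, _ = iseq.simulate_sequences(spec)
        noisy = iseq.add_gamma_noise(clean, 1.0, seed=22)
        dec = iseq.fit(noisy, L=30, threshold=0.3, K0=8, restarts=1,
                       iters=200, seed=0)
        assert dec.n_sequences == 1

    def test_deterministic_given_seed(self, small_synth):
        spec, clean, _ = small_synth
        V = clean.values[:, :600]
        kw = dict(L=spec.L, threshold=0.3, K0=5, restarts=1, iters=40, seed=3)
        d1 = iseq.fit(V, **kw)
        d2 = iseq.fit(V, **kw)
        np.testing.assert_array_equal(d1.W.values, d2.W.values)
        np.testing.assert_array_equal(d1.H.values, d2.H.values)

    def test_error_trace_monotone_and_similarity_contract(self, small_synth):
        spec, clean, _ = small_synth
        V = clean.values[:, :600]
        dec = iseq.fit(V, L=spec.L, threshold=0.3, K0=5, restarts=1,
                       iters=50, seed=4)
        tr = dec.error_trace
        assert all(b <= a + 1e-9 for a, b in zip(tr, tr[1:]))
        K = dec.n_sequences
        assert np.allclose(np.diag(dec.similarity), 1.0)
        off = dec.similarity[~np.eye(K, dtype=bool)]
        assert (off <= 0.3 + 1e-12).all()
        assert (dec.W.values >= 0).all() and (dec.H.values >= 0).all()


def test_detected_k_robust_to_increased_snr():
    """K recovery holds when the S/N ratio is raised threefold (S/N = 1 is
    exercised by the benchmark suite)."""
    spec = iseq.SyntheticSpec(K=5, N_s=100, T=3000, L=50, snr_k=3.0, seed=7)
    clean, _ = iseq.simulate_sequences(spec)
    noisy = iseq.add_gamma_noise(clean, 3.0, seed=1007)
    dec = iseq.fit(noisy, L=50, threshold=0.3, K0=20, restarts=2,
                   iters=200, seed=0)
    assert dec.n_sequences == 5
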