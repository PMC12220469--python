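"""Convolutive NMF with the Itakura-Saito divergence (the iSeq engine).

The recording ``V`` (neurons x time) is approximated by the tensor
convolution ``U`` of a pattern tensor ``W`` (neurons x sequences x window)
with an intensity matrix ``H`` (sequences x extended time):

    U[n, t] = sum_k sum_l W[n, k, l] * H[k, t - l + (L - 1)]

``H`` covers virtual times ``-(L-1) .. T-1`` so that sequences beginning
before the first recorded frame are representable.  The reconstruction
error is the Itakura-Saito divergence, whose scale invariance matches the
multiplicative (signal-proportional) noise of calcium imaging.  Factors
are fitted by multiplicative updates; whenever a joint update would
increase the divergence, the candidate is repeatedly pulled halfway back
toward the previous factors until the error is non-increasing, which
guarantees a monotone error trace.

The number of sequences K is determined automatically: fitting starts
from a deliberately large K, the overlap of every fitted sequence with
the data is computed (a transpose tensor convolution), pairs of sequences
whose overlap traces have a time-shifted Pearson correlation above a
threshold are merged, and the survivors are refined.  A staged
compression pipeline (fit on an L-binned matrix, select the densest 10%
of compressed frames, fit at full window on those frames, merge, then
refine on the full matrix) keeps the whole procedure cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_preproc import ActivityMatrix

__all__ = [
    "EPS",
    "PatternTensor",
    "IntensityMatrix",
    "Decomposition",
    "tensor_convolve",
    "is_divergence",
    "damped_update",
    "overlap_matrix",
    "sequence_similarity",
    "merge_sequences",
    "fit",
]

#: Floor applied inside ratios and logs of the IS divergence and the
#: multiplicative updates; the divergence is undefined at exact zeros.
EPS = 1e-8


@dataclass
class PatternTensor:
    """Non-negative N x K x L tensor of sequence shapes (``W``)."""

    values: np.ndarray
    window_seconds: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("pattern tensor must be 3-D (neurons, sequences, window)")
        if (self.values < 0).any():
            raise ValueError("pattern tensor must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_sequences(self) -> int:
        return self.values.shape[1]

    @property
    def window(self) -> int:
        return self.values.shape[2]


@dataclass
class IntensityMatrix:
    """Non-negative K x (T + L - 1) matrix of sequence activations (``H``).

    Column ``j`` corresponds to virtual time ``j - offset`` with
    ``offset = L - 1``, so the first ``offset`` columns describe
    activations that started before the recording.
    """

    values: np.ndarray
    offset: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("intensity matrix must be 2-D")
        if (self.values < 0).any():
            raise ValueError("intensity matrix must be non-negative")
        if not 0 <= self.offset < self.values.shape[1] + 1:
            raise ValueError("offset out of range")

    @property
    def n_sequences(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1] - self.offset


@dataclass
class Decomposition:
    """Result of :func:`fit`: factors, error trace and similarity matrix."""

    W: PatternTensor
    H: IntensityMatrix
    error_trace: list = field(default_factory=list)
    similarity: np.ndarray | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_sequences(self) -> int:
        return self.W.n_sequences


def _as_array(x):
    return x.values if isinstance(x, (ActivityMatrix, PatternTensor, IntensityMatrix)) else np.asarray(x, float)


def _stacked_shifts(Hv: np.ndarray, L: int, T: int) -> np.ndarray:
    """Stack the L time-shifted versions of every H row into a (K*L, T) matrix.

    Row ``k*L + l`` holds ``H[k, t - l + (L-1)]`` for ``t = 0..T-1``, so the
    tensor convolution collapses into one matrix product.
    """
    S = np.lib.stride_tricks.sliding_window_view(Hv, T, axis=1)  # (K, L, T)
    return S[:, ::-1, :].reshape(Hv.shape[0] * L, T)


def tensor_convolve(W, H) -> np.ndarray:
    """Reconstruct ``U`` (N x T) from ``W`` (N x K x L) and ``H`` (K x T+L-1)."""
    Wv, Hv = _as_array(W), _as_array(H)
    N, K, L = Wv.shape
    if Hv.shape[0] != K:
        raise ValueError(f"W has K={K} sequences but H has {Hv.shape[0]} rows")
    T = Hv.shape[1] - L + 1
    if T < 1:
        raise ValueError("H has fewer columns than the window length requires")
    return Wv.reshape(N, K * L) @ _stacked_shifts(Hv, L, T)


def is_divergence(V, U, floor: float = EPS) -> float:
    """Itakura-Saito divergence ``sum v/u - log(v/u) - 1`` with flooring."""
    v = np.maximum(_as_array(V), floor)
    u = np.maximum(_as_array(U), floor)
    if v.shape != u.shape:
        raise ValueError(f"shape mismatch {v.shape} vs {u.shape}")
    r = v / u
    return float(np.sum(r - np.log(r) - 1.0))


def _update_W(Wv, Hv, A, B, floor):
    """Multiplicative W update: element-wise ratio of the shifted products."""
    N, K, L = Wv.shape
    T = A.shape[1]
    St = _stacked_shifts(Hv, L, T)
    prod = (np.concatenate([A, B], axis=0) @ St.T).reshape(2, N, K, L)
    return Wv * prod[0] / np.maximum(prod[1], floor)


def _transpose_convolve(Wv, A):
    """Transpose tensor convolution: G[k, j] = sum_{n,l} W[n,k,l] A[n, j+l-(L-1)].

    ``A`` is N x T (or a stack of such maps along a leading axis); the
    result is K x (T + L - 1) per map, aligned with ``H``.
    """
    stacked = A.ndim == 3
    As = A if stacked else A[None]
    n_maps, N, T = As.shape
    K, L = Wv.shape[1], Wv.shape[2]
    Apad = np.zeros((N, n_maps * (T + 2 * (L - 1))))
    span = T + 2 * (L - 1)
    for i in range(n_maps):
        Apad[:, i * span + L - 1 : i * span + L - 1 + T] = As[i]
    M = (Wv.reshape(N, K * L).T @ Apad).reshape(K, L, n_maps, span)
    G = np.zeros((n_maps, K, T + L - 1))
    for l in range(L):
        G += np.moveaxis(M[:, l, :, l : l + T + L - 1], 1, 0)
    return G if stacked else G[0]


def damped_update(V, W, H, floor: float = EPS, max_halvings: int = 50,
                  _U: np.ndarray | None = None, _return_U: bool = False):
    """One guaranteed-descent multiplicative update of ``W`` and ``H``.

    Applies the printed multiplicative rules jointly (both computed from
    the current reconstruction), then, if the IS divergence increased,
    repeatedly replaces the candidate with the midpoint between old and
    candidate factors until the divergence no longer exceeds its previous
    value.  Returns ``(W', H', D')`` as plain arrays plus the new error.

    ``_U`` may carry the cached reconstruction of the current factors;
    with ``_return_U`` the accepted candidate's reconstruction is
    appended to the return value (both used by the fit loop to avoid
    recomputing convolutions).
    """
    Vv, Wv, Hv = _as_array(V), _as_array(W), _as_array(H)
    U = tensor_convolve(Wv, Hv) if _U is None else _U
    D0 = is_divergence(Vv, U, floor)
    if not np.isfinite(D0):
        raise FloatingPointError("non-finite divergence before update")
    Uc = np.maximum(U, floor)
    A = Vv / Uc**2
    B = 1.0 / Uc

    Wcand = _update_W(Wv, Hv, A, B, floor)
    G = _transpose_convolve(Wv, np.stack([A, B]))
    Hcand = Hv * G[0] / np.maximum(G[1], floor)
    if not (np.isfinite(Wcand).all() and np.isfinite(Hcand).all()):
        raise FloatingPointError("non-finite values produced by multiplicative update")

    out = (Wv, Hv, D0, U)
    for _ in range(max_halvings):
        Ucand = tensor_convolve(Wcand, Hcand)
        D1 = is_divergence(Vv, Ucand, floor)
        if D1 <= D0:
            out = (Wcand, Hcand, D1, Ucand)
            break
        Wcand = 0.5 * (Wv + Wcand)
        Hcand = 0.5 * (Hv + Hcand)
    # if no descent within the halving budget, the previous factors stand
    return out if _return_U else out[:3]


def overlap_matrix(W, V) -> np.ndarray:
    """Sliding overlap of each sequence with the data.

    ``R[k, t] = sum_{n,l} W[n,k,l] V[n, t+l]`` with zero padding at the
    right edge; each row is the time series of the match between one
    sequence's pattern and the recording.
    """
    Wv, Vv = _as_array(W), _as_array(V)
    N, K, L = Wv.shape
    T = Vv.shape[1]
    Vpad = np.zeros((N, T + L - 1))
    Vpad[:, :T] = Vv
    R = np.zeros((K, T))
    for l in range(L):
        R += Wv[:, :, l].T @ Vpad[:, l : l + T]
    return R


def _shifted_pearson(a: np.ndarray, b: np.ndarray, max_shift: int) -> float:
    """Max Pearson correlation of ``a`` with ``b`` over shifts in [-s, s].

    For shift ``s >= 0`` the overlapping support is ``a[s:]`` against
    ``b[:T-s]`` (and symmetrically for negative shifts).  All shifts are
    evaluated at once: the cross terms come from an FFT correlation and
    the segment moments from prefix sums.
    """
    from scipy.signal import fftconvolve

    T = len(a)
    max_shift = min(max_shift, T - 2)
    s = np.arange(-max_shift, max_shift + 1)
    m = (T - np.abs(s)).astype(float)
    cross = fftconvolve(a, b[::-1])[T - 1 + s]
    ca, ca2 = np.concatenate([[0], np.cumsum(a)]), np.concatenate([[0], np.cumsum(a * a)])
    cb, cb2 = np.concatenate([[0], np.cumsum(b)]), np.concatenate([[0], np.cumsum(b * b)])
    lo_a = np.maximum(s, 0)
    hi_a = np.minimum(T, T + s)
    lo_b = np.maximum(-s, 0)
    hi_b = np.minimum(T, T - s)
    sum_a = ca[hi_a] - ca[lo_a]
    sum_a2 = ca2[hi_a] - ca2[lo_a]
    sum_b = cb[hi_b] - cb[lo_b]
    sum_b2 = cb2[hi_b] - cb2[lo_b]
    var_a = sum_a2 - sum_a**2 / m
    var_b = sum_b2 - sum_b**2 / m
    cov = cross - sum_a * sum_b / m
    tol = 1e-12 * max(sum_a2.max(), sum_b2.max(), 1.0)
    ok = (var_a > tol) & (var_b > tol)
    if not ok.any():
        return 0.0
    r = cov[ok] / np.sqrt(var_a[ok] * var_b[ok])
    return float(np.clip(r.max(), -1.0, 1.0))


def sequence_similarity(R: np.ndarray, max_shift: int) -> np.ndarray:
    """Pairwise max time-shifted Pearson correlation between overlap rows.

    Rows with zero variance get similarity 0 to everything (a flat overlap
    trace cannot evidence "the same sequence"); the diagonal is 1.
    """
    R = np.asarray(R, float)
    K = R.shape[0]
    sim = np.eye(K)
    const = R.std(axis=1) == 0
    for i in range(K):
        for j in range(i + 1, K):
            if const[i] or const[j]:
                v = 0.0
            else:
                v = _shifted_pearson(R[i], R[j], max_shift)
            sim[i, j] = sim[j, i] = v
    return sim


def _sequence_energy(Wv, Hv, k) -> float:
    """Total mass of sequence k's partial reconstruction ``U_k``."""
    return float(tensor_convolve(Wv[:, k : k + 1, :], Hv[k : k + 1]).sum())


def merge_sequences(W, H, sim: np.ndarray, threshold: float = 0.3,
                    mode: str = "drop"):
    """Merge sequence pairs whose similarity exceeds ``threshold``.

    Iteratively takes the most similar pair above threshold and, in
    ``"drop"`` mode, removes the member whose partial reconstruction
    carries less total energy; ``"sum"`` mode adds the dropped member's
    factors onto the survivor.  Returns ``(W', H', keep_indices)``.
    """
    Wv, Hv = _as_array(W).copy(), _as_array(H).copy()
    sim = np.asarray(sim, float).copy()
    keep = list(range(Wv.shape[1]))
    while len(keep) > 1:
        S = sim.copy()
        np.fill_diagonal(S, -np.inf)
        i, j = np.unravel_index(np.argmax(S), S.shape)
        if S[i, j] <= threshold:
            break
        ei = _sequence_energy(Wv, Hv, i)
        ej = _sequence_energy(Wv, Hv, j)
        drop, survivor = (i, j) if ei < ej else (j, i)
        if mode == "sum":
            Wv[:, survivor, :] += Wv[:, drop, :]
            Hv[survivor] += Hv[drop]
        elif mode != "drop":
            raise ValueError(f"unknown merge mode {mode!r}")
        Wv = np.delete(Wv, drop, axis=1)
        Hv = np.delete(Hv, drop, axis=0)
        sim = np.delete(np.delete(sim, drop, axis=0), drop, axis=1)
        keep.pop(drop)
    return Wv, Hv, keep


def _random_factors(rng, N, K, L, T, target_mean, floor=EPS):
    """Uniform(0,1) init for W and H, with H scaled so mean(U) ~ mean(V)."""
    W = rng.uniform(size=(N, K, L))
    H = rng.uniform(size=(K, T + L - 1))
    U = tensor_convolve(W, H)
    m = U.mean()
    if m > 0 and target_mean > 0:
        H *= target_mean / m
    return W, np.maximum(H, floor)


def _run_updates(V, W, H, n_iter, trace=None, floor=EPS):
    U = None
    for _ in range(n_iter):
        W, H, D, U = damped_update(V, W, H, floor=floor, _U=U, _return_U=True)
        if trace is not None:
            trace.append(D)
    return W, H


def _bin_columns(V: np.ndarray, L: int) -> np.ndarray:
    Tc = V.shape[1] // L
    return V[:, : Tc * L].reshape(V.shape[0], Tc, L).mean(axis=2)


def fit(V, L: int, threshold: float = 0.3, K0: int = 20, restarts: int = 10,
        iters: int = 200, seed: int = 0, merge_mode: str = "drop",
        hd_fraction: float = 0.1, floor: float = 1e-3) -> Decomposition:
    """Fit the full staged decomposition and determine K automatically.

    Per restart: (1) fit mini factors (window 2) on the L-binned matrix
    for 30% of ``iters``; (2) take the compressed frames with the largest
    mini-intensity until ``hd_fraction`` of compressed frames is reached,
    restore their original full-resolution columns into a high-density
    matrix, and fit full-window factors on it for 30%; (3) merge
    sequences whose time-shifted overlap correlation against the full
    matrix exceeds ``threshold`` and refine for 10%; (4) refine on the
    full matrix for the remaining 30%.  The restart with the smallest
    final IS divergence wins; its post-merge similarity matrix (all
    off-diagonals at or below ``threshold``) is reported.

    ``floor`` is the divergence/update floor *relative to the grand mean*
    of ``V`` (the matrix is normalized internally and ``H`` scaled back
    on return).  The default 1e-3 keeps the many exact-zero entries of
    sparse calcium data from dominating the objective; it both stabilizes
    the factors and preserves the calibrated merge-threshold range.
    """
    Vv = _as_array(V)
    N, T = Vv.shape
    if T < L:
        raise ValueError(f"T={T} is shorter than the window L={L}")
    if K0 < 1:
        raise ValueError("K0 must be >= 1")
    # normalize by the grand mean so the whole pipeline (including the
    # absolute floor) is exactly scale-equivariant; H is scaled back at
    # the end -- the IS objective itself is scale-invariant
    v_scale = float(Vv.mean())
    if v_scale <= 0:
        raise ValueError("activity matrix is identically zero")
    Vv = Vv / v_scale
    n1 = int(0.3 * iters)
    n2 = int(0.3 * iters)
    n3 = int(0.1 * iters)
    n4 = iters - n1 - n2 - n3

    Vc = _bin_columns(Vv, L)
    Tc = Vc.shape[1]
    n_sel = max(1, int(round(hd_fraction * Tc)))

    best = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        stage_traces: dict[str, list] = {"mini": [], "hd": [], "post_merge": [], "full": []}

        # --- stage 1: mini factors on the compressed matrix -------------
        Wm, Hm = _random_factors(rng, N, K0, 2, Tc, Vc.mean(), floor)
        Wm, Hm = _run_updates(Vc, Wm, Hm, n1, stage_traces["mini"], floor)

        # --- stage 2: high-density matrix at full resolution ------------
        frame_score = Hm[:, 1 : Tc + 1].max(axis=0)   # activation starting at each frame
        sel = np.sort(np.argsort(frame_score)[::-1][:n_sel])
        Vhd = np.concatenate([Vv[:, f * L : (f + 1) * L] for f in sel], axis=1)
        Thd = Vhd.shape[1]

        # warm start from the mini factors: spread each mini lag across its
        # half-window span (jittered to break lag symmetry), so surplus
        # factors inherit real-sequence structure and later merge away
        # instead of persisting as unmergeable noise factors
        W = np.empty((N, K0, L))
        half = L // 2
        W[:, :, :half] = Wm[:, :, 0:1] / max(half, 1)
        W[:, :, half:] = Wm[:, :, 1:2] / max(L - half, 1)
        W *= rng.uniform(0.5, 1.5, size=W.shape)
        H = rng.uniform(size=(K0, Thd + L - 1))
        U0 = tensor_convolve(W, H)
        if U0.mean() > 0 and Vhd.mean() > 0:
            H *= Vhd.mean() / U0.mean()
        H = np.maximum(H, floor)
        W, H = _run_updates(Vhd, W, H, n2, stage_traces["hd"], floor)

        # --- stage 3: determine K by overlap similarity, refine ---------
        # the overlap for K determination is taken against the original
        # matrix: short high-density excerpts inflate the null of the
        # max-shifted correlation and would over-merge distinct sequences
        R = overlap_matrix(W, Vv)
        sim = sequence_similarity(R, max_shift=L - 1)
        W, H, keep = merge_sequences(W, H, sim, threshold, merge_mode)
        sim_kept = sim[np.ix_(keep, keep)]
        if W.shape[1] == 0:
            warnings.warn("all sequences merged away; K collapsed to 0")
        else:
            W, H = _run_updates(Vhd, W, H, n3, stage_traces["post_merge"], floor)

        # --- stage 4: refine on the full-resolution matrix --------------
        K = W.shape[1]
        Hf = rng.uniform(size=(K, T + L - 1))
        if K:
            Hf *= 0.1 * max(H.mean(), floor)
            # place fitted activations back at their original positions
            for c, f in enumerate(sel):
                src = H[:, L - 1 + c * L : L - 1 + (c + 1) * L]
                Hf[:, L - 1 + f * L : L - 1 + f * L + src.shape[1]] = src
            Hf = np.maximum(Hf, floor)
            W, Hf = _run_updates(Vv, W, Hf, n4, stage_traces["full"], floor)
            D = is_divergence(Vv, tensor_convolve(W, Hf), floor)
        else:
            Hf = np.zeros((0, T + L - 1))
            D = is_divergence(Vv, np.zeros_like(Vv), floor)

        if best is None or D < best[0]:
            best = (D, W, Hf, stage_traces, r, sim_kept)

    D, W, H, stage_traces, r_best, simf = best
    H = H * v_scale
    if W.shape[1] == 0:
        warnings.warn("decomposition collapsed to K = 0 sequences")

    return Decomposition(
        W=PatternTensor(W),
        H=IntensityMatrix(H, offset=L - 1),
        error_trace=list(stage_traces["full"]),
        similarity=simf,
        seed=seed,
        config=dict(L=L, threshold=threshold, K0=K0, restarts=restarts,
                    iters=iters, merge_mode=merge_mode, hd_fraction=hd_fraction,
                    best_restart=r_best, final_divergence=D,
                    stage_traces=stage_traces),
    )
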