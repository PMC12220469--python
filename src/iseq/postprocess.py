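"""Canonicalizing detected sequences and converting intensity to spike intensity.

Sharpening removes the temporal smear a convolutive factorization leaves
in the pattern tensor: each neuron of a sequence is reduced to a single
relative intensity (``w_int``, summing to 1 over the sequence) and a
single relative timing within the window (``w_tim``, in frames).  Spike
intensity rescales each sequence's activation trace by its own slow
moving average, ``s = (h - mu) / mu`` capped at 1, yielding a scale-free,
onset-emphasizing signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IntensityMatrix, PatternTensor, _as_array

__all__ = ["SharpSequence", "SpikeIntensity", "sharpen", "spike_intensity"]


@dataclass
class SharpSequence:
    """One sharpened sequence: per-neuron intensity and timing vectors."""

    w_int: np.ndarray          # sums to 1
    w_tim: np.ndarray          # integer frames in [0, L)
    reference_neuron: int
    window: int

    def __post_init__(self) -> None:
        self.w_int = np.asarray(self.w_int, float)
        self.w_tim = np.asarray(self.w_tim, int)
        if (self.w_int < 0).any():
            raise ValueError("w_int must be non-negative")
        if abs(self.w_int.sum() - 1.0) > 1e-9:
            raise ValueError("w_int must sum to 1")
        if ((self.w_tim < 0) | (self.w_tim >= self.window)).any():
            raise ValueError("w_tim must lie in [0, L)")


@dataclass
class SpikeIntensity:
    """K x T matrix of moving-average-scaled sequence activation."""

    values: np.ndarray
    frame_rate: float
    window_s: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("spike intensity must be 2-D")

    @property
    def n_sequences(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _best_shift(trace: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Shift of ``trace`` relative to ``ref`` (positive = trace lags)."""
    T = len(ref)
    best_s, best_c = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            x, y = trace[s:], ref[: T - s]
        else:
            x, y = trace[: T + s], ref[-s:]
        if len(x) < 2:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        c = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
        if c > best_c:
            best_c, best_s = c, s
    return best_s


def sharpen(W, H):
    """Sharpen every sequence of a decomposition.

    For sequence ``k`` the partial reconstruction ``U_k`` is built from
    slice ``k`` of ``W`` and row ``k`` of ``H``.  ``w_int`` is the
    normalized row sums of ``U_k``; the neuron with the largest intensity
    is the reference; each neuron's ``w_tim`` is the correlation-maximizing
    shift of its trace relative to the reference, re-anchored into
    ``[0, L)``.  ``H`` is rescaled per row (scalar least squares against
    ``U_k``) so the sharpened factors reconstruct approximately the same
    partial activity.

    Returns ``(sequences, W_sharp, H_adjusted)``.
    """
    from scipy.signal import fftconvolve

    Wv = _as_array(W)
    Hobj = H if isinstance(H, IntensityMatrix) else None
    Hv = _as_array(H).copy()
    N, K, L = Wv.shape
    Wsharp = np.zeros_like(Wv)
    seqs = []
    for k in range(K):
        # full (extended-time) partial reconstruction, so every activation
        # contributes its whole transient regardless of the neuron's lag
        Uk = fftconvolve(Wv[:, k, :], Hv[k][None, :], axes=1)
        Uk = np.maximum(Uk, 0.0)
        w_int = Uk.sum(axis=1)
        total = w_int.sum()
        if total <= 0:
            raise ValueError(f"sequence {k} reconstructs to all zeros")
        w_int = w_int / total
        ref = int(np.argmax(w_int))
        shifts = np.zeros(N, dtype=int)
        active = Uk.std(axis=1) > 0
        for n in range(N):
            if n == ref or not active[n]:
                continue
            shifts[n] = _best_shift(Uk[n], Uk[ref], L - 1)
        w_tim = shifts - shifts[active].min() if active.any() else shifts
        w_tim = np.clip(w_tim, 0, L - 1)

        Wk = np.zeros((N, L))
        Wk[np.arange(N), w_tim] = w_int
        Uk_sharp = fftconvolve(Wk, Hv[k][None, :], axes=1)
        denom = float(np.sum(Uk_sharp * Uk_sharp))
        scale = float(np.sum(Uk_sharp * Uk)) / denom if denom > 0 else 1.0
        Hv[k] *= max(scale, 0.0)
        Wsharp[:, k, :] = Wk
        seqs.append(SharpSequence(w_int=w_int, w_tim=w_tim,
                                  reference_neuron=ref, window=L))
    W_out = PatternTensor(Wsharp, window_seconds=getattr(W, "window_seconds", 10.0))
    H_out = (IntensityMatrix(Hv, offset=Hobj.offset) if Hobj is not None else Hv)
    return seqs, W_out, H_out


def _truncated_moving_average(h: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average; windows are truncated at the edges."""
    T = len(h)
    csum = np.concatenate([[0.0], np.cumsum(h)])
    t = np.arange(T)
    lo = np.maximum(t - half, 0)
    hi = np.minimum(t + half, T - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def spike_intensity(H, frame_rate: float, window_s: float = 10.0,
                    cap: float = 1.0) -> SpikeIntensity:
    """Scale each sequence activation by its local moving average.

    ``s_k(t) = (h_k(t) - mu_k(t)) / mu_k(t)`` where ``mu`` is a centered
    moving average over ``+-window_s`` (edge-truncated); frames with
    ``mu = 0`` give ``s = 0``; values are capped at ``cap``.  If ``H`` is
    an :class:`IntensityMatrix` only the recorded frames (columns from
    ``offset`` on) are used.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if isinstance(H, IntensityMatrix):
        Hv = H.values[:, H.offset :]
    else:
        Hv = np.asarray(H, float)
    half = max(1, int(round(window_s * frame_rate)))
    S = np.zeros_like(Hv)
    for k in range(Hv.shape[0]):
        mu = _truncated_moving_average(Hv[k], half)
        pos = mu > 0
        S[k, pos] = (Hv[k, pos] - mu[pos]) / mu[pos]
    np.minimum(S, cap, out=S)
    return SpikeIntensity(S, frame_rate=frame_rate, window_s=window_s)
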