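"""Behavioural event extraction and spatial maps of sequence activity.

The Y-maze floor is partitioned into 2 cm x 2 cm blocks (190 valid blocks
for the default mask).  A sequence's location vector ``l^k(tau)[b]`` is
the average spike intensity ``tau`` frames before the animal occupies
block ``b``; via Bayes it is proportional to the distribution of the
animal's position ``tau`` frames after the sequence fires.  Spatial
specificity is summarized by a Gini coefficient over blocks, and
Success/Failure separation by Euclidean and Mahalanobis distances
between event-aligned trajectory ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_preproc import SessionRecord
from .postprocess import SpikeIntensity

__all__ = [
    "YMazeMask",
    "LocationVector",
    "TrajectorySet",
    "classify_licks",
    "location_vector",
    "gini",
    "trajectory_distance",
]

BLOCK_CM = 2.0


def _default_cells() -> list[tuple[int, int]]:
    """Block coordinates of the default Y-maze mask (exactly 190 cells).

    The maze is laid out with a horizontal trunk (columns 1-8, six blocks
    wide) ending in a small port alcove (column 0), and two 45-degree
    arms (columns 9-20, six blocks wide measured vertically) that are
    mirror images about the trunk axis.
    """
    cells = set()
    for y in range(13, 17):              # port alcove
        cells.add((0, y))
    for x in range(1, 9):                # trunk
        for y in range(12, 18):
            cells.add((x, y))
    for x in range(9, 21):               # arms (upper + mirrored lower)
        r0 = 13 + (x - 9)
        for y in range(r0, r0 + 6):
            cells.add((x, y))
            cells.add((x, 29 - y))
    return sorted(cells)


@dataclass
class YMazeMask:
    """Valid-block geometry of the maze on a 2 cm grid."""

    cells: list = field(default_factory=_default_cells)
    block_cm: float = BLOCK_CM

    def __post_init__(self) -> None:
        self.cells = sorted(tuple(c) for c in self.cells)
        self._index = {c: i for i, c in enumerate(self.cells)}
        self.nx = max(c[0] for c in self.cells) + 1
        self.ny = max(c[1] for c in self.cells) + 1

    @property
    def n_blocks(self) -> int:
        return len(self.cells)

    def block_of(self, x_cm: float, y_cm: float) -> int:
        bx = int(np.floor(x_cm / self.block_cm))
        by = int(np.floor(y_cm / self.block_cm))
        try:
            return self._index[(bx, by)]
        except KeyError:
            raise ValueError(f"position ({x_cm}, {y_cm}) cm falls outside the maze mask")

    def blocks_of(self, x_cm, y_cm) -> np.ndarray:
        return np.array([self.block_of(xi, yi) for xi, yi in zip(x_cm, y_cm)])

    def center_cm(self, b: int) -> tuple[float, float]:
        bx, by = self.cells[b]
        return ((bx + 0.5) * self.block_cm, (by + 0.5) * self.block_cm)

    def grid(self, flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        g = np.full((self.nx, self.ny), fill)
        for i, (bx, by) in enumerate(self.cells):
            g[bx, by] = flat[i]
        return g

    def ungrid(self, g: np.ndarray) -> np.ndarray:
        return np.array([g[bx, by] for bx, by in self.cells])

    def mirror_y_permutation(self) -> np.ndarray:
        """Block permutation mirroring the maze about its horizontal axis."""
        perm = np.empty(self.n_blocks, dtype=int)
        for i, (bx, by) in enumerate(self.cells):
            j = self._index.get((bx, self.ny - 1 - by))
            if j is None:
                raise ValueError("mask is not symmetric under Y inversion")
            perm[i] = j
        return perm

    def port_blocks(self) -> np.ndarray:
        xmin = min(c[0] for c in self.cells)
        return np.array([i for i, c in enumerate(self.cells) if c[0] == xmin])

    def zone_blocks(self, which: str = "upper") -> np.ndarray:
        xmax = max(c[0] for c in self.cells)
        mid = (self.ny - 1) / 2
        sel = []
        for i, (bx, by) in enumerate(self.cells):
            if bx >= xmax - 1:
                if (which == "upper" and by > mid) or (which == "lower" and by < mid):
                    sel.append(i)
        return np.array(sel)


@dataclass
class LocationVector:
    """Per-sequence L x B tables of average spike intensity by position.

    ``values`` has shape (K, L, B); ``missing`` (L, B) flags blocks with
    no occupancy samples at a given shift.
    """

    values: np.ndarray
    missing: np.ndarray
    mask: YMazeMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("location vector values must be (K, L, B)")
        if self.values.shape[2] != self.mask.n_blocks:
            raise ValueError("block dimension does not match the mask")


@dataclass
class TrajectorySet:
    """Event-aligned windows: array of shape (n_events, T_w, d)."""

    windows: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, float)
        if self.windows.ndim != 3:
            raise ValueError("trajectory set must be (events, frames, dims)")

    @property
    def n_events(self) -> int:
        return self.windows.shape[0]


def classify_licks(session: SessionRecord, refractory_s: float = 10.0):
    """Split licks into counted Success / Failure events.

    Rewarded licks are always Success events.  An unrewarded lick counts
    as a Failure only if it occurs at least ``refractory_s`` after the
    previous lick (rewarded or not); closer unrewarded licks are "just in
    case" licks and are not counted.  Every lick, counted or not, resets
    the refractory clock.
    """
    bad = np.flatnonzero(session.reward & ~session.lick)
    if bad.size:
        raise ValueError(f"reward without lick at frame {bad[0]}")
    refractory = refractory_s * session.frame_rate
    success, failure = [], []
    t_last = None
    for t in np.flatnonzero(session.lick):
        if session.reward[t]:
            success.append(int(t))
        elif t_last is None or (t - t_last) >= refractory:
            failure.append(int(t))
        t_last = t
    session.success_events = success
    session.failure_events = failure
    return success, failure


def location_vector(S: SpikeIntensity, session: SessionRecord,
                    mask: YMazeMask | None = None, L: int = 50,
                    smooth: bool = True, sigma: float = 1.0) -> LocationVector:
    """Average spike intensity by occupied block at each time shift.

    ``l^k(tau)[b]`` averages ``s_k(t - tau)`` over the frames ``t`` when
    the animal occupies block ``b``.  Occupancy-weighted Gaussian
    smoothing (5x5 kernel, sigma in blocks, renormalized at the mask
    boundary) is applied to each map; blocks never visited are flagged
    missing (NaN).
    """
    if mask is None:
        mask = YMazeMask()
    T = S.n_frames
    if session.n_frames != T:
        raise ValueError("spike intensity and session disagree on frame count")
    if T == 0:
        raise ValueError("empty session")
    blocks = mask.blocks_of(session.x, session.y)
    K, B = S.n_sequences, mask.n_blocks
    values = np.zeros((K, L, B))
    missing = np.zeros((L, B), dtype=bool)
    for tau in range(L):
        t_idx = np.arange(tau, T)
        b_idx = blocks[t_idx]
        counts = np.bincount(b_idx, minlength=B).astype(float)
        sums = np.zeros((K, B))
        for k in range(K):
            sums[k] = np.bincount(b_idx, weights=S.values[k, t_idx - tau], minlength=B)
        if smooth:
            cg = gaussian_filter(mask.grid(counts), sigma=sigma, truncate=2.0)
            counts_s = mask.ungrid(cg)
            for k in range(K):
                sg = gaussian_filter(mask.grid(sums[k]), sigma=sigma, truncate=2.0)
                sums[k] = mask.ungrid(sg)
            counts = counts_s
        empty = counts <= 1e-12
        missing[tau] = empty
        with np.errstate(invalid="ignore", divide="ignore"):
            values[:, tau, :] = np.where(empty, np.nan, sums / np.maximum(counts, 1e-12))
    return LocationVector(values=values, missing=missing, mask=mask)


def gini_slice(vec: np.ndarray, n_blocks: int | None = None) -> float:
    """Gini coefficient of one map slice by the double-sum formula.

    Missing entries count as 0; if negative values occur the map is
    shifted by its minimum first (the formula presumes non-negative
    shares).  An all-zero map has Gini 0.
    """
    x = np.nan_to_num(np.asarray(vec, float), nan=0.0)
    N = len(x) if n_blocks is None else n_blocks
    if x.min() < 0:
        x = x - x.min()
    total = x.sum()
    if total <= 0:
        return 0.0
    xs = np.sort(x)
    i = np.arange(1, len(xs) + 1)
    # sum_{b,beta} |x_b - x_beta| = 2 * sum_i (2i - n - 1) x_(i)
    mad = 2.0 * np.sum((2 * i - len(xs) - 1) * xs)
    return float(mad / (2.0 * N * total))


def gini(lv: LocationVector) -> np.ndarray:
    """Average Gini coefficient over time shifts, per sequence."""
    K, L, B = lv.values.shape
    out = np.zeros(K)
    for k in range(K):
        out[k] = float(np.mean([gini_slice(lv.values[k, tau], B) for tau in range(L)]))
    return out


def trajectory_distance(S_set: TrajectorySet, F_set: TrajectorySet,
                        mode: str = "euclidean", covariance: str = "failure",
                        ridge: float = 1e-8) -> float:
    """Time-averaged distance between Success and Failure trajectory sets.

    ``euclidean``: mean over frames of the 2-norm between the per-frame
    mean trajectories.  ``mahalanobis``: the same difference whitened by
    the per-frame covariance of the Failure set (or the pooled covariance
    of both sets), with ridge regularization ``Sigma + ridge*I``; with
    ``ridge = 0`` a singular covariance raises.
    """
    S = S_set.windows
    F = F_set.windows
    if S.shape[1:] != F.shape[1:]:
        raise ValueError("trajectory sets disagree on window length or dimension")
    m, T, d = S.shape
    n = F.shape[0]
    if m < 1 or n < 1:
        raise ValueError("each set needs at least one event")
    sbar = S.mean(axis=0)
    fbar = F.mean(axis=0)
    diff = sbar - fbar
    if mode == "euclidean":
        return float(np.mean(np.linalg.norm(diff, axis=1)))
    if mode != "mahalanobis":
        raise ValueError(f"unknown mode {mode!r}")
    if n < 2:
        raise ValueError("mahalanobis mode needs >= 2 Failure events")
    total = 0.0
    for t in range(T):
        if covariance == "failure":
            Sig = np.cov(F[:, t, :], rowvar=False, ddof=1).reshape(d, d)
        elif covariance == "pooled":
            Ss = np.cov(S[:, t, :], rowvar=False, ddof=1).reshape(d, d) if m > 1 else np.zeros((d, d))
            Sf = np.cov(F[:, t, :], rowvar=False, ddof=1).reshape(d, d)
            Sig = ((m - 1) * Ss + (n - 1) * Sf) / (m + n - 2)
        else:
            raise ValueError(f"unknown covariance {covariance!r}")
        Sig = Sig + ridge * np.eye(d)
        try:
            sol = np.linalg.solve(Sig, diff[t])
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular covariance at frame {t}; pass ridge > 0")
        total += float(np.sqrt(max(diff[t] @ sol, 0.0)))
    return total / T
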