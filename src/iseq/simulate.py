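"""Synthetic calcium-sequence data and a toy Y-maze session.

Each embedded sequence is driven by one master calcium trace following
an exponential-decay transient model: the trace decays as dx/dt = -x/tau
and jumps by 1 at frames where an independent uniform draw falls below
the firing probability ``p``.  Every cell of a sequence shows the master
trace delayed by its own random shift in ``[0, L)``.  Multiplicative
noise ``n(t) ~ Gamma(k, 1/k)`` (mean 1, variance 1/k) reproduces the
signal-proportional noise of calcium imaging; the signal-to-noise ratio
of the noisy data equals the gamma shape ``k``.

:func:`simulate_session` adds a toy behavioural fixture: a random walk
on the 190-block Y-maze mask with zone/lick/reward flags and sequence
intensities time-locked to chosen behavioural events, so every
downstream stage (location vectors, SND, decoding, consistency) is
testable with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behaviour_maps import YMazeMask
from .core import IntensityMatrix
from .io_preproc import ActivityMatrix, SessionRecord

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "simulate_sequences",
    "add_gamma_noise",
    "simulate_session",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic sequence generator.

    Defaults are the generator's standard conditions: 100 cells per
    sequence, decay constant tau = 2.0 frames, per-frame firing
    probability p = 0.05, window L = 50 frames, gamma shape (S/N) k = 1.
    """

    K: int = 5
    N_s: int = 100
    T: int = 3000
    L: int = 50
    tau: float = 2.0
    p: float = 0.05
    snr_k: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 0 or self.N_s < 1 or self.T < 1 or self.L < 1:
            raise ValueError("K >= 0, N_s >= 1, T >= 1, L >= 1 required")
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.tau <= 0 or self.snr_k <= 0:
            raise ValueError("tau and snr_k must be positive")


@dataclass
class GroundTruth:
    """Which cells form each sequence, their shifts, and the clean matrix."""

    membership: dict
    shifts: np.ndarray
    clean: ActivityMatrix
    masters: np.ndarray = field(default=None, repr=False)


def _master_trace(rng: np.random.Generator, T: int, tau: float, p: float) -> np.ndarray:
    """Euler integration of dx/dt = -x/tau + delta(r(t) < p), unit step."""
    fires = rng.uniform(size=T) < p
    x = np.zeros(T)
    decay = 1.0 - 1.0 / tau
    prev = 0.0
    for t in range(T):
        prev = prev * decay + (1.0 if fires[t] else 0.0)
        x[t] = prev
    return x


def simulate_sequences(spec: SyntheticSpec):
    """Generate the clean embedded-sequence matrix and its ground truth.

    Returns ``(ActivityMatrix, GroundTruth)`` with ``N = K * N_s`` rows;
    cells of sequence k occupy the contiguous block ``k*N_s..(k+1)*N_s-1``
    and each shows the sequence's master trace delayed by a uniform
    integer shift in ``[0, L)``.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.K * spec.N_s
    V = np.zeros((max(N, 1), spec.T))
    membership: dict[int, np.ndarray] = {}
    shifts = np.zeros(max(N, 1), dtype=int)
    masters = np.zeros((spec.K, spec.T))
    for k in range(spec.K):
        master = _master_trace(rng, spec.T, spec.tau, spec.p)
        masters[k] = master
        cells = np.arange(k * spec.N_s, (k + 1) * spec.N_s)
        membership[k] = cells
        cell_shifts = rng.integers(0, spec.L, size=spec.N_s)
        shifts[cells] = cell_shifts
        for c, s in zip(cells, cell_shifts):
            if s == 0:
                V[c] = master
            else:
                V[c, s:] = master[:-s]
    am = ActivityMatrix(V, frame_rate=5.0)
    return am, GroundTruth(membership=membership, shifts=shifts, clean=am,
                           masters=masters)


def add_gamma_noise(V: ActivityMatrix, snr_k: float, seed: int = 0) -> ActivityMatrix:
    """Multiply every entry by an independent Gamma(k, 1/k) draw (mean 1)."""
    if snr_k <= 0:
        raise ValueError("snr_k must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.gamma(shape=snr_k, scale=1.0 / snr_k, size=V.values.shape)
    return ActivityMatrix(V.values * noise, frame_rate=V.frame_rate,
                          neuron_ids=V.neuron_ids)


def _random_walk_blocks(rng, mask: YMazeMask, T: int) -> np.ndarray:
    """Task-like walk: shuttle between the arm zones and the lick port.

    Waypoints alternate between a randomly chosen zone tip and the port
    (with occasional random detours), with short dwell periods at each
    waypoint, emulating the trained shuttling behaviour.
    """
    cells = mask.cells
    index = {c: i for i, c in enumerate(cells)}
    neigh = []
    for (bx, by) in cells:
        ns = [index[c] for c in ((bx + 1, by), (bx - 1, by), (bx, by + 1), (bx, by - 1))
              if c in index]
        neigh.append(ns)
    zones = np.concatenate([mask.zone_blocks("upper"), mask.zone_blocks("lower")])
    ports = mask.port_blocks()

    def new_target(go_port: bool) -> int:
        if rng.uniform() < 0.15:                       # occasional detour
            return int(rng.integers(len(cells)))
        pool = ports if go_port else zones
        return int(pool[rng.integers(len(pool))])

    pos = int(ports[0])
    go_port = False
    target = new_target(go_port)
    dwell = 0
    out = np.empty(T, dtype=int)
    for t in range(T):
        out[t] = pos
        if dwell > 0:
            dwell -= 1
            continue
        if pos == target:
            go_port = not go_port
            target = new_target(go_port)
            dwell = int(rng.integers(2, 10))
            continue
        tx, ty = cells[target]
        options = neigh[pos]
        if options and rng.uniform() < 0.9:
            dists = [abs(cells[o][0] - tx) + abs(cells[o][1] - ty) for o in options]
            pos = options[int(np.argmin(dists))]
        elif options:
            pos = options[int(rng.integers(len(options)))]
    return out


def simulate_session(T: int, seed: int = 0, K: int = 3, L: int = 50,
                     frame_rate: float = 5.0, success_prob: float = 0.7,
                     lag_frames: int = 5, mask: YMazeMask | None = None,
                     embed=None):
    """Toy Y-maze session with behaviour-locked sequence intensities.

    The animal performs a waypoint-seeking random walk over the maze
    blocks; reaching the port triggers a lick, rewarded with probability
    ``success_prob``.  Sequence 0 fires ``lag_frames`` before zone
    entries, sequence 1 before licks, and any further sequences fire at
    random times.  Returns ``(SessionRecord, IntensityMatrix)`` where the
    intensity matrix has the usual extended time axis (offset ``L - 1``).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if mask is None:
        mask = YMazeMask()
    if embed is not None:
        K = max(K, len(embed.membership))
    rng = np.random.default_rng(seed)
    blocks = _random_walk_blocks(rng, mask, T)
    centers = np.array([mask.center_cm(b) for b in blocks])
    jitter = rng.uniform(-0.8, 0.8, size=centers.shape)
    x, y = centers[:, 0] + jitter[:, 0], centers[:, 1] + jitter[:, 1]

    zone = set(mask.zone_blocks("upper")) | set(mask.zone_blocks("lower"))
    port = set(mask.port_blocks())
    in_zone = np.array([b in zone for b in blocks])
    at_port = np.array([b in port for b in blocks])

    lick = np.zeros(T, dtype=bool)
    reward = np.zeros(T, dtype=bool)
    last_lick = -np.inf
    refractory = 2.0 * frame_rate
    for t in range(T):
        if at_port[t] and (t - last_lick) >= refractory:
            lick[t] = True
            last_lick = t
            if rng.uniform() < success_prob:
                reward[t] = True
    session = SessionRecord(x=x, y=y, in_zone=in_zone, lick=lick, reward=reward,
                            frame_rate=frame_rate)

    zone_entries = np.flatnonzero(in_zone & ~np.roll(in_zone, 1))
    if in_zone[0]:
        zone_entries = np.union1d(zone_entries, [0])
    lick_frames = np.flatnonzero(lick)
    H = np.zeros((K, T + L - 1))
    offset = L - 1
    kernel = np.exp(-np.arange(6) / 2.0)

    def stamp(row: int, frames: np.ndarray) -> None:
        for f in frames:
            start = f - lag_frames
            col = start + offset
            for i, kv in enumerate(kernel):
                if 0 <= col + i < T + offset:
                    H[row, col + i] += kv

    if K > 0:
        stamp(0, zone_entries)
    if K > 1:
        stamp(1, lick_frames)
    for k in range(2, K):
        stamp(k, rng.integers(0, T, size=max(1, T // 100)))
    return session, IntensityMatrix(H, offset=offset)
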