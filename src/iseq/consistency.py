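"""Day-to-day consistency of neuronal sequences.

Two sequences recorded on different days can resemble each other in two
independent ways: the *population* of cells that fire (the sharpened
intensity vectors ``w_int`` compared over a shared neuron registry) and
the *pathway* the animal takes while they fire (the location vectors).
If the cells that form a sequence were stable, population similarity and
pathway similarity would correlate across sequence pairs; the
correlation is tested against a null built by shuffling cell identities.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "population_similarity",
    "pathway_similarity",
    "consistency_correlation",
]


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance vector has no z-score")
    return (v - v.mean()) / sd


def population_similarity(w_a, w_b) -> float:
    """Cosine similarity of z-scored cell-intensity vectors.

    Both vectors must index the same neuron registry (cells matched by
    ID across days).
    """
    a, b = _zscore(w_a), _zscore(w_b)
    if a.shape != b.shape:
        raise ValueError("intensity vectors must share the neuron registry")
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def pathway_similarity(l_a, l_b, invert_y: bool = False, mask=None) -> float:
    """Time-averaged cosine similarity of z-scored location vectors.

    ``l_a`` and ``l_b`` are (L, B) tables.  Each whole vector is z-scored
    once (missing entries as 0), then cosine similarity is averaged over
    the time shifts; flat slices (all-zero maps) are skipped with a warning.
    With ``invert_y`` the second map's blocks are mirrored about the maze
    axis (``mask`` supplies the permutation; the default maze is used
    when omitted).
    """
    a = np.nan_to_num(np.asarray(l_a, float), nan=0.0)
    b = np.nan_to_num(np.asarray(l_b, float), nan=0.0)
    if a.shape != b.shape:
        raise ValueError("location vectors must share the block grid and L")
    if invert_y:
        if mask is None:
            from .behaviour_maps import YMazeMask
            mask = YMazeMask()
        b = b[:, mask.mirror_y_permutation()]
    dead = (np.ptp(a, axis=1) == 0) | (np.ptp(b, axis=1) == 0)
    a = _zscore(a.ravel()).reshape(a.shape)
    b = _zscore(b.ravel()).reshape(b.shape)
    sims = []
    for tau in range(a.shape[0]):
        if dead[tau]:
            warnings.warn(f"all-zero map at shift {tau}; skipped")
            continue
        na, nb = np.linalg.norm(a[tau]), np.linalg.norm(b[tau])
        if na == 0 or nb == 0:
            continue
        sims.append(float(a[tau] @ b[tau] / (na * nb)))
    if not sims:
        raise ValueError("no usable time shifts")
    return float(np.mean(sims))


def consistency_correlation(w_day_a: list, w_day_b: list, l_day_a: list,
                            l_day_b: list, shuffles: int = 1000, seed: int = 0,
                            invert_y: bool = False, mask=None):
    """Correlation between population and pathway similarity across days.

    ``w_day_*`` are lists of per-sequence cell-intensity vectors (shared
    neuron registry) and ``l_day_*`` the matching lists of (L, B)
    location vectors.  Over the Cartesian product of day-a and day-b
    sequences, the Pearson correlation between population similarity and
    pathway similarity is computed; the null distribution permutes the
    cell IDs of each day's intensity vectors ``shuffles`` times (one
    independent permutation per day and draw) and recomputes r.  Returns
    ``(r, null)``; with ``shuffles = 0`` the null array is empty.
    """
    if len(w_day_a) != len(l_day_a) or len(w_day_b) != len(l_day_b):
        raise ValueError("intensity and location lists must pair up per day")
    pairs = [(i, j) for i in range(len(w_day_a)) for j in range(len(w_day_b))]
    if len(pairs) < 3:
        raise ValueError("need at least 3 sequence pairs for a correlation")
    path = np.array([pathway_similarity(l_day_a[i], l_day_b[j],
                                        invert_y=invert_y, mask=mask)
                     for i, j in pairs])

    def pop_sims(wa, wb):
        return np.array([population_similarity(wa[i], wb[j]) for i, j in pairs])

    r = float(stats.pearsonr(pop_sims(w_day_a, w_day_b), path)[0])
    if shuffles <= 0:
        return r, np.empty(0)
    rng = np.random.default_rng(seed)
    n = len(w_day_a[0])
    null = np.empty(shuffles)
    for s in range(shuffles):
        pa = rng.permutation(n)
        pb = rng.permutation(n)
        wa = [w[pa] for w in w_day_a]
        wb = [w[pb] for w in w_day_b]
        null[s] = stats.pearsonr(pop_sims(wa, wb), path)[0]
    return r, null
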