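"""Sequential neuronal dynamics: PCA trajectories and Procrustes alignment.

Spike intensities of the detected sequences are projected onto their top
principal components; the trajectory through that subspace during the
window preceding each Success or Failure lick is the event's sequential
neuronal dynamics (SND).  To compare SND distances across days (whose
subspaces differ in orientation and scale), each day's average
Failure-SND is Procrustes-aligned to a reference day's, and the fitted
similarity transform is applied to that day's Success-SNDs before
distances are measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .behaviour_maps import TrajectorySet, trajectory_distance
from .postprocess import SpikeIntensity

__all__ = [
    "ProcrustesTransform",
    "snd_project",
    "event_trajectories",
    "procrustes_align",
    "compare_snd",
]


@dataclass
class ProcrustesTransform:
    """Similarity transform ``x -> s * x @ R + t``."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(X, float) @ self.rotation + self.translation


def snd_project(S: SpikeIntensity, d: int = 2):
    """Project spike intensities onto the top ``d`` principal components.

    Returns ``(scores, explained_variance_ratio)`` where ``scores`` is
    T x d.  Component signs are fixed so the largest-magnitude loading of
    each component is positive, making runs reproducible.
    """
    X = S.values.T                      # frames x sequences
    if X.shape[1] < d:
        raise ValueError(f"need at least {d} sequences for a {d}-D projection")
    pca = PCA(n_components=d)
    scores = pca.fit_transform(X)
    for j in range(d):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores, pca.explained_variance_ratio_


def event_trajectories(scores: np.ndarray, events, window_frames: int,
                       kind: str = "") -> TrajectorySet:
    """Extract the ``window_frames`` of scores preceding each event."""
    scores = np.asarray(scores, float)
    wins = []
    for e in events:
        if e < window_frames:
            warnings.warn(f"event at frame {e} precedes the window; skipped")
            continue
        wins.append(scores[e - window_frames : e])
    if not wins:
        return TrajectorySet(np.zeros((0, window_frames, scores.shape[1])), kind=kind)
    return TrajectorySet(np.stack(wins), kind=kind)


def procrustes_align(X: np.ndarray, Y: np.ndarray,
                     allow_reflection: bool = True):
    """Align point set ``X`` onto reference ``Y`` by a similarity transform.

    Both sets are mean-centred and Frobenius-normalized; the rotation is
    ``R = V U^T`` from the SVD of ``Xbar^T Ybar``, the scale is
    ``||Ytilde||_F / ||Xtilde||_F`` and the translation
    ``mu_Y - s mu_X R``.  With ``allow_reflection=False`` the determinant
    of ``R`` is forced to +1 by flipping the last singular direction.
    Returns ``(ProcrustesTransform, aligned X)``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("point sets must share a shape")
    muX, muY = X.mean(axis=0), Y.mean(axis=0)
    Xt, Yt = X - muX, Y - muY
    nX, nY = np.linalg.norm(Xt), np.linalg.norm(Yt)
    if nX == 0 or nY == 0:
        raise ValueError("degenerate point set: all points identical")
    Xb, Yb = Xt / nX, Yt / nY
    U, _, Vt = np.linalg.svd(Xb.T @ Yb)
    R = (Vt.T @ U.T).T                  # equals V U^T applied as x @ R
    if not allow_reflection and np.linalg.det(R) < 0:
        Vt = Vt.copy()
        Vt[-1] *= -1
        R = (Vt.T @ U.T).T
    s = nY / nX
    t = muY - s * muX @ R
    tf = ProcrustesTransform(rotation=R, scale=s, translation=t)
    return tf, tf.apply(X)


def compare_snd(success_by_day: dict, failure_by_day: dict, reference_day,
                ridge: float = 1e-8) -> dict:
    """Cross-day Success/Failure SND distances in a common reference frame.

    For each day, the day's average Failure-SND is Procrustes-aligned to
    the reference day's average Failure-SND; the fitted transform is then
    applied to that day's Success-SNDs, and Euclidean and Mahalanobis
    trajectory distances are computed against the reference-frame
    Failure set.  Days missing either event kind are skipped.
    """
    ref_F = failure_by_day[reference_day]
    ref_mean = ref_F.windows.mean(axis=0)
    out = {}
    for day, F in failure_by_day.items():
        S = success_by_day.get(day)
        if S is None or S.n_events == 0 or F.n_events == 0:
            warnings.warn(f"day {day!r} lacks Success or Failure events; skipped")
            continue
        day_mean = F.windows.mean(axis=0)
        tf, _ = procrustes_align(day_mean, ref_mean)
        S_aligned = TrajectorySet(
            np.stack([tf.apply(w) for w in S.windows]), kind=S.kind)
        F_aligned = TrajectorySet(
            np.stack([tf.apply(w) for w in F.windows]), kind=F.kind)
        out[day] = {
            "transform": tf,
            "euclidean": trajectory_distance(S_aligned, ref_F, mode="euclidean"),
            "mahalanobis": trajectory_distance(S_aligned, ref_F,
                                               mode="mahalanobis", ridge=ridge),
            "failure_residual": float(np.linalg.norm(tf.apply(day_mean) - ref_mean)),
            "_failure_aligned": F_aligned,
        }
    return out
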