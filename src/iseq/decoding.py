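"""Class-balanced decoding of behaviour from sequence spike intensities.

Binary behaviours (zone occupancy, licking, reward) are far rarer in the
1 class than the 0 class, so squared error is reweighted per class:

    E_bin = |Z|/(2|Z0|) * sum_{t in Z0} (z - zhat)^2
          + |Z|/(2|Z1|) * sum_{t in Z1} (z - zhat)^2

For continuous targets in [0, 1] (maze coordinates) the criterion
generalizes to two weights alpha (frames with z <= 0.5) and beta
(frames with z > 0.5) chosen from the target's moments so that the
constant-0.5 "null decoder" again attains the minimum value 0.25 per
frame, and so that on a binary target the continuous criterion reduces
exactly to the binary one.  A decoder only carries information if its
balanced validation error drops clearly below the 0.25 null level.

The decoder itself is a small recurrent network (two recurrent layers of
width 8, a linear read-out and a logistic output) trained by Adam with
backpropagation through time on the balanced criterion, using the middle
50% of the recording for training and the flanks for validation, with
early stopping at the validation minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .postprocess import SpikeIntensity

__all__ = [
    "BehaviourTarget",
    "BalancedError",
    "balanced_error",
    "null_decoder_error",
    "train_decoder",
    "DecodingResult",
]


@dataclass
class BehaviourTarget:
    """Per-frame behaviour values in [0, 1]; binary or continuous."""

    z: np.ndarray
    kind: str = "binary"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        if self.kind not in ("binary", "continuous"):
            raise ValueError("kind must be 'binary' or 'continuous'")
        if self.kind == "binary":
            if not np.isin(self.z, (0.0, 1.0)).all():
                raise ValueError("binary target must contain only 0 and 1")
        elif ((self.z < 0) | (self.z > 1)).any():
            raise ValueError("continuous target must lie in [0, 1]")


class BalancedError(NamedTuple):
    total: float
    per_frame: float


def _balanced_weights(z: np.ndarray, kind: str) -> np.ndarray:
    """Per-frame weights of the class-balanced squared-error criterion."""
    T = len(z)
    w = np.empty(T)
    if kind == "binary":
        n1 = int(np.sum(z == 1))
        n0 = T - n1
        if n0 == 0 or n1 == 0:
            raise ValueError("binary target must contain both classes")
        w[z == 0] = T / (2.0 * n0)
        w[z == 1] = T / (2.0 * n1)
        return w
    neg = z <= 0.5
    pos = ~neg
    Zn, Zp = int(neg.sum()), int(pos.sum())
    if Zn == 0 or Zp == 0:
        raise ValueError("continuous target needs values on both sides of 0.5")
    Qn, Rn = float(z[neg].sum()), float((z[neg] ** 2).sum())
    Qp, Rp = float(z[pos].sum()), float((z[pos] ** 2).sum())
    denom_b = (8.0 * (Qp * Rn - Qn * Rp) - 4.0 * Zn * (Qp - Rp)
               + 4.0 * Zp * (Qn - Rn) - 2.0 * (Qn * Zp - Qp * Zn))
    if denom_b == 0:
        raise ValueError("degenerate target: balanced weights are undefined")
    beta = T * (Zn - 2.0 * Qn) / denom_b
    denom_a = 4.0 * Rn - 4.0 * Qn + Zn
    if denom_a == 0:
        raise ValueError("degenerate target: balanced weights are undefined")
    alpha = (T - beta * (4.0 * Rp - 4.0 * Qp + Zp)) / denom_a
    w[neg] = alpha
    w[pos] = beta
    return w


def balanced_error(z: BehaviourTarget, z_hat) -> BalancedError:
    """Class-balanced squared error between target and prediction."""
    z_hat = np.asarray(z_hat, float)
    if z_hat.shape != z.z.shape:
        raise ValueError("target and prediction lengths differ")
    w = _balanced_weights(z.z, z.kind)
    total = float(np.sum(w * (z.z - z_hat) ** 2))
    return BalancedError(total=total, per_frame=total / len(z.z))


def null_decoder_error(z: BehaviourTarget) -> BalancedError:
    """Balanced error of the constant-0.5 (chance baseline) decoder."""
    return balanced_error(z, np.full_like(z.z, 0.5))


# --------------------------------------------------------------------------
# recurrent decoder (two recurrent layers, width 8, logistic read-out)
# --------------------------------------------------------------------------

def _init_params(rng, n_in: int, hidden: int) -> dict:
    def mat(fan_in, shape):
        return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
    return {
        "W1x": mat(n_in, (n_in, hidden)), "W1h": mat(hidden, (hidden, hidden)),
        "b1": np.zeros(hidden),
        "W2x": mat(hidden, (hidden, hidden)), "W2h": mat(hidden, (hidden, hidden)),
        "b2": np.zeros(hidden),
        "wo": mat(hidden, (hidden,)), "bo": np.zeros(1),
    }


def _forward(params, X):
    """X: (batch, steps, features) -> predictions plus cached activations."""
    B, S, F = X.shape
    hdim = params["b1"].shape[0]
    h1 = np.zeros((B, hdim))
    h2 = np.zeros((B, hdim))
    h1s = np.empty((S, B, hdim))
    h2s = np.empty((S, B, hdim))
    for s in range(S):
        h1 = np.tanh(X[:, s] @ params["W1x"] + h1 @ params["W1h"] + params["b1"])
        h2 = np.tanh(h1 @ params["W2x"] + h2 @ params["W2h"] + params["b2"])
        h1s[s] = h1
        h2s[s] = h2
    logit = h2 @ params["wo"] + params["bo"][0]
    yhat = 1.0 / (1.0 + np.exp(-logit))
    return yhat, (X, h1s, h2s, yhat)


def _backward(params, cache, dyhat):
    """Backprop through time; returns gradients for every parameter."""
    X, h1s, h2s, yhat = cache
    S, B, hdim = h1s.shape
    g = {k: np.zeros_like(v) for k, v in params.items()}
    dlogit = dyhat * yhat * (1.0 - yhat)
    g["wo"] = h2s[-1].T @ dlogit
    g["bo"][0] = dlogit.sum()
    dh2 = np.outer(dlogit, params["wo"])
    dh1 = np.zeros((B, hdim))
    for s in range(S - 1, -1, -1):
        dpre2 = dh2 * (1.0 - h2s[s] ** 2)
        h2_prev = h2s[s - 1] if s > 0 else np.zeros((B, hdim))
        h1_prev = h1s[s - 1] if s > 0 else np.zeros((B, hdim))
        g["W2x"] += h1s[s].T @ dpre2
        g["W2h"] += h2_prev.T @ dpre2
        g["b2"] += dpre2.sum(axis=0)
        dh1 = dh1 + dpre2 @ params["W2x"].T
        dpre1 = dh1 * (1.0 - h1s[s] ** 2)
        g["W1x"] += X[:, s].T @ dpre1
        g["W1h"] += h1_prev.T @ dpre1
        g["b1"] += dpre1.sum(axis=0)
        dh2 = dpre2 @ params["W2h"].T
        dh1 = dpre1 @ params["W1h"].T
    return g


class _Adam:
    def __init__(self, params, lr=1e-2, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class DecodingResult:
    mean_error: float            # mean over reps of the best per-frame validation error
    rep_errors: list
    null_error: float
    predictions: np.ndarray      # best rep's predictions on all decodable frames
    frames: np.ndarray           # the frame indices those predictions refer to
    config: dict = field(default_factory=dict)


def train_decoder(S: SpikeIntensity, z: BehaviourTarget, window_s: float = 10.0,
                  step_s: float = 0.2, reps: int = 10, seed: int = 0,
                  epochs: int = 500, patience: int = 50, lr: float = 1e-2,
                  hidden: int = 8) -> DecodingResult:
    """Train the recurrent decoder and report balanced validation error.

    The input at frame ``t`` is the spike-intensity window from
    ``t - window_s`` to ``t - step_s`` (50 steps at the default 0.2 s
    binning).  Training uses the middle 50% of frames, validation the
    flanking quarters; training stops at the epoch minimizing the
    balanced validation error.  The whole procedure is repeated ``reps``
    times with distinct seeds and the mean of the per-rep best
    validation errors (per frame) is returned.
    """
    w = int(round(window_s * S.frame_rate))
    T = S.n_frames
    if T <= w + 4:
        raise ValueError("recording too short for the decoding window")
    if len(z.z) != T:
        raise ValueError("target length must match the spike-intensity frames")

    frames = np.arange(w, T)
    X = np.empty((len(frames), w, S.n_sequences))
    for i, t in enumerate(frames):
        X[i] = S.values[:, t - w : t].T
    zv = z.z[frames]

    lo, hi = int(0.25 * T), int(0.75 * T)
    train_mask = (frames >= lo) & (frames < hi)
    val_mask = ~train_mask
    for name, msk in (("training", train_mask), ("validation", val_mask)):
        sub = zv[msk]
        if z.kind == "binary" and (not (sub == 0).any() or not (sub == 1).any()):
            raise ValueError(f"class absent from the {name} split")
        if z.kind == "continuous" and (not (sub <= 0.5).any() or not (sub > 0.5).any()):
            raise ValueError(f"{name} split lacks values on one side of 0.5")

    w_train = _balanced_weights(zv[train_mask], z.kind)
    z_train = zv[train_mask]
    X_train, X_val = X[train_mask], X[val_mask]
    z_val = BehaviourTarget(zv[val_mask], kind=z.kind)

    rep_errors = []
    best_overall = None
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        params = _init_params(rng, S.n_sequences, hidden)
        opt = _Adam(params, lr=lr)
        best_err, best_params, since = np.inf, None, 0
        for _ in range(epochs):
            yhat, cache = _forward(params, X_train)
            dyhat = 2.0 * w_train * (yhat - z_train)
            grads = _backward(params, cache, dyhat)
            opt.step(params, grads)
            yv, _ = _forward(params, X_val)
            err = balanced_error(z_val, yv).per_frame
            if err < best_err - 1e-9:
                best_err, since = err, 0
                best_params = {k: v.copy() for k, v in params.items()}
            else:
                since += 1
                if since >= patience:
                    break
        rep_errors.append(best_err)
        if best_overall is None or best_err < best_overall[0]:
            best_overall = (best_err, best_params)

    pred, _ = _forward(best_overall[1], X)
    return DecodingResult(
        mean_error=float(np.mean(rep_errors)),
        rep_errors=[float(e) for e in rep_errors],
        null_error=null_decoder_error(BehaviourTarget(zv, kind=z.kind)).per_frame,
        predictions=pred,
        frames=frames,
        config=dict(window_s=window_s, step_s=step_s, reps=reps, seed=seed,
                    epochs=epochs, patience=patience, lr=lr, hidden=hidden),
    )
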