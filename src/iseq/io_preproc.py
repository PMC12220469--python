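"""Reading, writing and preprocessing of activity matrices and behaviour tracks.

An :class:`ActivityMatrix` is the non-negative neurons x time-frames matrix
``V`` produced by a cell-extraction pipeline (e.g. HOTARU-extracted dF/F
traces captured at 20 Hz).  Before factorization the matrix is binned in
time (default 4 frames = 0.2 s), each cell is scaled so the mean of its
nonzero entries is 1, and extreme values are capped at three standard
deviations above the nonzero mean.

Behaviour tracks (:class:`SessionRecord`) carry per-frame x/y position in
cm together with zone / lick / reward flags; Success and Failure lick
events are derived by :func:`iseq.behaviour_maps.classify_licks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ActivityMatrix",
    "SessionRecord",
    "load_activity",
    "save_activity",
    "preprocess_activity",
    "load_session",
    "save_session",
]


@dataclass
class ActivityMatrix:
    """Non-negative per-neuron activity over time.

    Parameters
    ----------
    values
        Array of shape ``(N, T)``; rows are neurons, columns time frames.
    frame_rate
        Sampling rate in frames per second (20 Hz raw, 5 Hz after the
        default 4-frame binning).
    neuron_ids
        Optional per-row labels, used to match cells across days.
    """

    values: np.ndarray
    frame_rate: float = 20.0
    neuron_ids: Sequence | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"activity must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("activity matrix must have at least one row and column")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            r, c = neg[0]
            raise ValueError(
                f"negative activity value {self.values[r, c]!r} at row {r}, col {c}"
            )
        if self.neuron_ids is not None and len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must equal the number of rows")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class SessionRecord:
    """Per-frame behaviour of one session.

    ``x``/``y`` are positions in cm; ``in_zone``, ``lick`` and ``reward``
    are per-frame booleans.  ``success_events`` / ``failure_events`` are
    frame indices of counted licks, filled in by ``classify_licks``.
    """

    x: np.ndarray
    y: np.ndarray
    in_zone: np.ndarray
    lick: np.ndarray
    reward: np.ndarray
    frame_rate: float = 5.0
    success_events: list = field(default_factory=list)
    failure_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.in_zone = np.asarray(self.in_zone, dtype=bool)
        self.lick = np.asarray(self.lick, dtype=bool)
        self.reward = np.asarray(self.reward, dtype=bool)
        T = len(self.x)
        for name in ("y", "in_zone", "lick", "reward"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"per-frame array {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {T}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.x)


def _looks_like_header(line: str, sep: str) -> bool:
    for tok in line.strip().split(sep):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def load_activity(path, format: str | None = None, transpose: bool = False,
                  frame_rate: float = 20.0) -> ActivityMatrix:
    """Load an activity matrix from delimited text or an HDF5 container.

    ``format`` is ``"delimited"`` or ``"array-container"``; when ``None`` it
    is inferred from the file suffix (``.h5``/``.hdf5`` -> container).  With
    ``transpose=True`` the stored array is read as time x neurons and
    transposed, mirroring extraction pipelines that store frames as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "array-container" if path.suffix.lower() in (".h5", ".hdf5") else "delimited"
    if format == "array-container":
        with h5py.File(path, "r") as f:
            values = np.asarray(f["activity"])
            frame_rate = float(f["activity"].attrs.get("frame_rate", frame_rate))
    elif format == "delimited":
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
        header = 0 if _looks_like_header(first, sep) else None
        try:
            df = pd.read_csv(path, sep=sep, header=header)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValueError(f"could not parse {path} as a delimited matrix: {exc}")
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {format!r}")
    if transpose:
        values = values.T
    return ActivityMatrix(values, frame_rate=frame_rate)


def save_activity(path, V: ActivityMatrix) -> None:
    """Write an activity matrix; HDF5 for ``.h5``/``.hdf5``, CSV otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("activity", data=V.values)
            d.attrs["frame_rate"] = V.frame_rate
    else:
        pd.DataFrame(V.values).to_csv(path, index=False, header=False)


def preprocess_activity(V: ActivityMatrix, bin_frames: int = 4, cap_sd: float = 3.0,
                        bin_stat: str = "mean") -> ActivityMatrix:
    """Bin in time, scale each cell's nonzero mean to 1, and cap outliers.

    Binning aggregates every ``bin_frames`` consecutive frames by
    ``bin_stat`` (``"mean"`` or ``"sum"``); trailing frames not filling a
    complete bin are dropped.  Per cell, nonzero entries are scaled so
    their mean is 1 (all-zero cells are left untouched), then capped at
    ``nonzero mean + cap_sd * nonzero SD`` where both statistics are
    computed once on the scaled, pre-cap values.  Cells with fewer than
    two nonzero samples have SD 0 and are capped at the nonzero mean.
    """
    if bin_frames < 1:
        raise ValueError("bin_frames must be >= 1")
    if cap_sd <= 0:
        raise ValueError("cap_sd must be positive")
    vals = V.values
    T = vals.shape[1]
    if T < bin_frames:
        raise ValueError(f"T={T} shorter than bin_frames={bin_frames}")
    Tb = T // bin_frames
    binned = vals[:, : Tb * bin_frames].reshape(vals.shape[0], Tb, bin_frames)
    if bin_stat == "mean":
        binned = binned.mean(axis=2)
    elif bin_stat == "sum":
        binned = binned.sum(axis=2)
    else:
        raise ValueError(f"unknown bin_stat {bin_stat!r}")

    out = binned.copy()
    for n in range(out.shape[0]):
        row = out[n]
        nz = row > 0
        if not nz.any():
            continue
        row[nz] /= row[nz].mean()
        mu = row[nz].mean()          # = 1 by construction
        sd = row[nz].std() if nz.sum() > 1 else 0.0
        np.minimum(row, mu + cap_sd * sd, out=row)
    return ActivityMatrix(out, frame_rate=V.frame_rate / bin_frames,
                          neuron_ids=V.neuron_ids)


_SESSION_COLS = ("x", "y", "in_zone", "lick", "reward")


def load_session(path, frame_rate: float = 5.0) -> SessionRecord:
    """Read a behaviour track from a delimited table with named columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _SESSION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"behaviour table missing columns {missing}")
    return SessionRecord(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        in_zone=df["in_zone"].to_numpy(bool),
        lick=df["lick"].to_numpy(bool),
        reward=df["reward"].to_numpy(bool),
        frame_rate=frame_rate,
    )


def save_session(path, session: SessionRecord) -> None:
    pd.DataFrame({
        "x": session.x, "y": session.y,
        "in_zone": session.in_zone.astype(int),
        "lick": session.lick.astype(int),
        "reward": session.reward.astype(int),
    }).to_csv(path, index=False)
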