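"""Per-second 8-parameter feature extraction and fixed-length epoching.

Each complete second of a recording is summarised by eight parameters: the
mean and the coefficient of variation (CV) of the X, Y and Z axes and of
the resultant force (the Euclidean magnitude of the 3-axis vector).  A
classification unit ("epoch") is a block of consecutive per-second feature
rows — 9 s by default, slid forward 1 s at a time — so a T-second feature
stream yields floor((T - L)/stride) + 1 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AccelTrace, LabelInterval

__all__ = [
    "FEATURE_COLUMNS",
    "Epoch",
    "InsufficientDataError",
    "resultant_force",
    "coefficient_of_variation",
    "per_second_features",
    "make_epochs",
    "select_feature_rows",
]

#: Column order of the 8-parameter feature vector.
FEATURE_COLUMNS = [
    "mean_x", "mean_y", "mean_z", "mean_r",
    "cv_x", "cv_y", "cv_z", "cv_r",
]

#: Default guard on the CV denominator, in g.  Axis means hover near zero
#: for several resting postures, which would make a raw sd/mean ratio
#: explode; the denominator is max(|mean|, floor).
DEFAULT_MEAN_FLOOR_G = 0.05


class InsufficientDataError(ValueError):
    """Too little data for the requested computation."""


@dataclass(frozen=True)
class Epoch:
    """A block of ``length_s`` consecutive per-second feature rows.

    ``values`` has shape (length_s, 8) in :data:`FEATURE_COLUMNS` order.
    """

    start_second: int
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(FEATURE_COLUMNS):
            raise ValueError("epoch values must have shape (length_s, 8)")
        if arr.shape[0] < 1:
            raise ValueError("epoch must contain at least one row")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def length_s(self) -> int:
        return self.values.shape[0]


def resultant_force(ax, ay, az):
    """Euclidean magnitude sqrt(ax^2 + ay^2 + az^2) of the 3-axis vector.

    Accepts scalars or arrays; raises on non-finite input.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise ValueError("non-finite acceleration value")
    out = np.sqrt(ax * ax + ay * ay + az * az)
    return float(out) if out.ndim == 0 else out


def coefficient_of_variation(values, mean_floor: float = DEFAULT_MEAN_FLOOR_G) -> float:
    """Population standard deviation over a floored absolute mean.

    The denominator is ``max(|mean|, mean_floor)`` so the ratio stays
    bounded when the mean is near zero; the standard deviation is the
    population (divide-by-n) form.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("coefficient of variation needs >= 2 values")
    if mean_floor <= 0:
        raise ValueError("mean_floor must be positive")
    sd = float(np.std(arr))
    denom = max(abs(float(np.mean(arr))), mean_floor)
    return sd / denom


def per_second_features(
    trace: AccelTrace, mean_floor: float = DEFAULT_MEAN_FLOOR_G
) -> pd.DataFrame:
    """Compute the 8 per-second parameters for every complete second.

    Seconds are half-open bins [k, k+1) anchored at the trace start; a
    trailing partial second is dropped.  Returns a DataFrame indexed by
    second (0-based) with columns :data:`FEATURE_COLUMNS`.
    """
    rate = trace.sampling_rate_hz
    per_bin = int(round(rate))
    if abs(rate - per_bin) > 1e-9:
        # non-integer rates would need per-bin sample-count bookkeeping
        raise ValueError("sampling rate must be an integer number of Hz")
    n_seconds = trace.n_samples // per_bin
    if n_seconds < 1:
        raise InsufficientDataError(
            f"trace duration {trace.duration_s:.3f} s is below 1 s"
        )
    xyz = trace.samples[: n_seconds * per_bin]
    r = resultant_force(xyz[:, 0], xyz[:, 1], xyz[:, 2])
    channels = np.column_stack([xyz, r]).reshape(n_seconds, per_bin, 4)
    means = channels.mean(axis=1)
    sds = channels.std(axis=1)
    denom = np.maximum(np.abs(means), mean_floor)
    cvs = sds / denom
    data = np.hstack([means, cvs])
    return pd.DataFrame(
        data, columns=FEATURE_COLUMNS, index=pd.RangeIndex(n_seconds, name="second")
    )


def make_epochs(
    features: pd.DataFrame | np.ndarray,
    length_s: int = 9,
    stride_s: int = 1,
) -> list[Epoch]:
    """Cut a per-second feature stream into sliding epochs.

    Epochs start at 0, stride_s, 2*stride_s, ... while a full window fits;
    a stream shorter than one window yields an empty list.
    """
    if length_s < 1:
        raise ValueError("length_s must be >= 1")
    if stride_s < 1:
        raise ValueError("stride_s must be >= 1")
    if isinstance(features, pd.DataFrame):
        offset = int(features.index[0]) if len(features) else 0
        arr = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    else:
        offset = 0
        arr = np.asarray(features, dtype=float)
    n = arr.shape[0]
    if n < length_s:
        return []
    starts = range(0, n - length_s + 1, stride_s)
    return [Epoch(offset + s, arr[s : s + length_s]) for s in starts]


def select_feature_rows(
    features: pd.DataFrame,
    intervals: list[LabelInterval],
    labels: set[str] | None = None,
) -> pd.DataFrame:
    """Rows of *features* whose second lies wholly inside a labelled interval.

    A second [k, k+1) is selected when some interval with an accepted label
    satisfies start_s <= k and k+1 <= end_s.  Used to gather reference rows
    (e.g. all clonic-phase seconds) from an annotated recording.
    """
    mask = np.zeros(len(features), dtype=bool)
    seconds = features.index.to_numpy()
    for iv in intervals:
        if labels is not None and iv.label not in labels:
            continue
        mask |= (seconds >= iv.start_s) & (seconds + 1 <= iv.end_s + 1e-9)
    return features.loc[mask]
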