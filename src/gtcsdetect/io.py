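"""Reading, writing and validating accelerometer recordings and interval labels.

Recordings are plain CSV with a single ``# start=<ISO8601>`` comment line,
a ``time,ax,ay,az`` header, time in seconds from recording start and
acceleration in units of g (the device's native unit; the nominal sensor
configuration is 50 Hz sampling at a +/- 8 g range).  Interval annotations
are CSV with header ``label,start_s,end_s``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AccelTrace",
    "LabelInterval",
    "FormatError",
    "SamplingRateError",
    "read_accel_csv",
    "write_accel_csv",
    "read_labels",
    "write_labels",
]

logger = logging.getLogger(__name__)

#: Allowed per-step deviation of the timestamp increment, as a fraction of
#: the nominal sampling interval.  Larger gaps are reported as errors rather
#: than silently resampled: the feature binning assumes a fixed rate.
SPACING_TOLERANCE_FRAC = 0.2


class FormatError(ValueError):
    """Malformed recording or annotation file."""


class SamplingRateError(ValueError):
    """Timestamps deviate from the declared uniform sampling rate."""


@dataclass(frozen=True)
class AccelTrace:
    """A uniformly sampled 3-axis acceleration recording.

    Parameters
    ----------
    sampling_rate_hz:
        Samples per second; must be positive.
    samples:
        Array of shape (n, 3) holding (ax, ay, az) in g.  Values outside
        ``+/- device_range_g`` are clipped on construction (real sensors
        saturate at their range) with a logged warning.
    device_range_g:
        Full-scale range of the sensor in g (nominal 8).
    start_time:
        Optional absolute wall-clock time of the first sample.
    """

    sampling_rate_hz: float
    samples: np.ndarray
    device_range_g: float = 8.0
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.device_range_g <= 0:
            raise ValueError("device_range_g must be positive")
        arr = np.asarray(self.samples, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 3)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values")
        n_clip = int(np.sum(np.abs(arr) > self.device_range_g))
        if n_clip:
            logger.warning(
                "clipping %d sample values outside +/- %g g", n_clip, self.device_range_g
            )
            arr = np.clip(arr, -self.device_range_g, self.device_range_g)
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Duration in seconds, exactly n_samples / sampling_rate_hz."""
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Seconds-from-start timestamp of every sample."""
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True, order=True)
class LabelInterval:
    """A half-open labelled time interval [start_s, end_s) in seconds."""

    start_s: float
    end_s: float
    label: str = field(compare=False)

    def __init__(self, label: str, start_s: float, end_s: float) -> None:
        # keyword-friendly constructor with (label, start, end) order
        object.__setattr__(self, "label", str(label))
        object.__setattr__(self, "start_s", float(start_s))
        object.__setattr__(self, "end_s", float(end_s))
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValueError(
                f"end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def read_accel_csv(path: str | Path, expected_rate_hz: float = 50.0) -> AccelTrace:
    """Read a recording CSV, validating uniform spacing at *expected_rate_hz*.

    Raises
    ------
    FormatError
        If required columns are missing or the file is empty.
    SamplingRateError
        If any timestamp step deviates from 1/rate by more than
        ``SPACING_TOLERANCE_FRAC/rate``; the message names the first
        offending sample index.
    """
    path = Path(path)
    if expected_rate_hz <= 0:
        raise ValueError("expected_rate_hz must be positive")
    start_time: datetime | None = None
    device_range = 8.0
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        header_line = first
        if first.startswith("#"):
            for token in first[1:].strip().split():
                key, _, value = token.partition("=")
                if key == "start" and value:
                    start_time = datetime.fromisoformat(value)
                elif key == "range_g" and value:
                    device_range = float(value)
            header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty recording file")
        columns = [c.strip() for c in header_line.strip().split(",")]
        required = ["time", "ax", "ay", "az"]
        missing = [c for c in required if c not in columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        df = pd.read_csv(fh, names=columns, float_precision="round_trip")
    if df.empty:
        return AccelTrace(
            sampling_rate_hz=expected_rate_hz,
            samples=np.empty((0, 3)),
            device_range_g=device_range,
            start_time=start_time,
        )
    for col in required:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    t = df["time"].to_numpy(dtype=float)
    dt_nominal = 1.0 / expected_rate_hz
    steps = np.diff(t)
    bad = np.nonzero(np.abs(steps - dt_nominal) > SPACING_TOLERANCE_FRAC * dt_nominal)[0]
    if bad.size:
        i = int(bad[0])
        raise SamplingRateError(
            f"{path}: timestamp step {steps[i]:.6g} s at sample index {i + 1} "
            f"deviates from nominal {dt_nominal:.6g} s"
        )
    samples = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    return AccelTrace(
        sampling_rate_hz=expected_rate_hz,
        samples=samples,
        device_range_g=device_range,
        start_time=start_time,
    )


def write_accel_csv(trace: AccelTrace, path: str | Path) -> Path:
    """Write *trace* as CSV; ``read_accel_csv`` recovers it exactly.

    Values are written with :func:`repr` precision so the write/read
    round-trip preserves every bit of the stored float64 samples.
    """
    path = Path(path)
    tokens = []
    if trace.start_time is not None:
        tokens.append(f"start={trace.start_time.isoformat()}")
    tokens.append(f"range_g={trace.device_range_g:g}")
    times = trace.times()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# " + " ".join(tokens) + "\n")
        fh.write("time,ax,ay,az\n")
        for t, (ax, ay, az) in zip(times, trace.samples):
            fh.write(f"{float(t)!r},{float(ax)!r},{float(ay)!r},{float(az)!r}\n")
    return path


def read_labels(path: str | Path) -> list[LabelInterval]:
    """Read interval annotations, returned sorted by start time.

    Intervals sharing a label must not overlap (one label = one track).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["label", "start_s", "end_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    intervals = [
        LabelInterval(row.label, row.start_s, row.end_s)
        for row in df.itertuples(index=False)
    ]
    intervals.sort()
    _check_no_overlap(intervals)
    return intervals


def write_labels(intervals: list[LabelInterval], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label,start_s,end_s\n")
        for iv in sorted(intervals):
            fh.write(f"{iv.label},{float(iv.start_s)!r},{float(iv.end_s)!r}\n")
    return path


def _check_no_overlap(sorted_intervals: list[LabelInterval]) -> None:
    last_end: dict[str, float] = {}
    for iv in sorted_intervals:
        prev = last_end.get(iv.label)
        if prev is not None and iv.start_s < prev:
            raise ValueError(
                f"overlapping intervals for label {iv.label!r} at t={iv.start_s}"
            )
        last_end[iv.label] = max(iv.end_s, last_end.get(iv.label, 0.0))
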