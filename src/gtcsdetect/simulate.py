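"""Synthetic 3-axis accelerometer signals for canine activity and seizures.

No recordings of the original study are available, so this module
generates labelled stand-in traces: the fifteen daily-activity classes
used to build the non-seizure reference, a two-phase tonic-clonic seizure,
and a sensor-displacement (harness rotation) artifact.

Each segment follows a deliberately simple signal model per axis:

    a(t) = offset + amp * sin(2*pi*f*t + phase) + N(0, noise_sd)

with a random phase per axis and Gaussian sensor noise.  Gravity appears
as a constant +1 g on the dorsoventral (Z) axis for upright postures and
rotates onto Y for lying-on-side postures, matching an interscapular
sensor mount (X craniocaudal, Y lateral, Z dorsoventral).  The per-class
parameter table below is an editable artifact choice — enough to exercise
every algorithmic path and give a clonic phase whose per-second
variability far exceeds any daily activity — not a biomechanical claim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .io import AccelTrace, LabelInterval

__all__ = [
    "MovementSpec",
    "Schedule",
    "DAILY_ACTIVITY_SPECS",
    "SEIZURE_SPECS",
    "TABLE_DOG_COUNTS",
    "simulate_segment",
    "simulate_gtcs",
    "simulate_day",
    "apply_displacement",
    "rotation_about_axis",
    "reference_collection_schedule",
    "day_schedule_with_seizures",
    "save_schedule",
    "load_schedule",
]


@dataclass(frozen=True)
class MovementSpec:
    """Signal-model parameters for one movement class.

    base_offset_g is the gravity projection plus postural offset per axis;
    osc_amp_g the sinusoid amplitude per axis; osc_freq_hz its frequency
    (must stay below Nyquist); noise_sd_g the sensor-noise standard
    deviation; duration_s the default segment length.
    """

    name: str
    base_offset_g: tuple[float, float, float]
    osc_freq_hz: float
    osc_amp_g: tuple[float, float, float]
    noise_sd_g: float
    duration_s: float = 9.0

    def __post_init__(self) -> None:
        if self.osc_freq_hz < 0:
            raise ValueError("osc_freq_hz must be >= 0")
        if any(a < 0 for a in self.osc_amp_g):
            raise ValueError("osc_amp_g components must be >= 0")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


# Fifteen daily-activity classes.  Static postures carry no oscillation;
# locomotion uses gait-range frequencies (walking ~1.8 Hz, running ~3 Hz),
# body-shaking a fast ~5 Hz burst.  Z offset ~1 g encodes gravity for
# upright postures; lying-on-side moves it onto Y.
DAILY_ACTIVITY_SPECS: dict[str, MovementSpec] = {
    spec.name: spec
    for spec in [
        MovementSpec("walking", (0.10, 0.00, 1.00), 1.8, (0.30, 0.20, 0.40), 0.05),
        MovementSpec("standing", (0.05, 0.00, 1.00), 0.0, (0.0, 0.0, 0.0), 0.02),
        MovementSpec("shaking", (0.00, 0.00, 1.00), 5.0, (0.70, 0.80, 0.70), 0.10, 2.0),
        MovementSpec("drinking", (0.30, 0.00, 0.95), 1.0, (0.10, 0.05, 0.10), 0.03),
        MovementSpec("running", (0.20, 0.00, 1.00), 3.0, (0.70, 0.40, 0.90), 0.10),
        MovementSpec("jumping_on_sofa", (0.20, 0.00, 1.00), 2.0, (0.50, 0.30, 1.00), 0.10, 3.0),
        MovementSpec("jumping_off_sofa", (-0.20, 0.00, 1.00), 2.0, (0.50, 0.30, 1.00), 0.10, 3.0),
        MovementSpec("lying_on_stomach", (0.00, 0.00, 1.00), 0.0, (0.0, 0.0, 0.0), 0.01),
        MovementSpec("lying_on_side", (0.00, 1.00, 0.05), 0.0, (0.0, 0.0, 0.0), 0.01),
        MovementSpec("scratching", (0.00, 0.10, 1.00), 4.0, (0.30, 0.50, 0.30), 0.05, 4.0),
        MovementSpec("playing_with_toy", (0.10, 0.00, 1.00), 2.5, (0.50, 0.50, 0.50), 0.08),
        MovementSpec("being_stroked", (0.00, 0.00, 1.00), 0.5, (0.05, 0.10, 0.10), 0.02),
        MovementSpec("sitting", (0.30, 0.00, 0.95), 0.0, (0.0, 0.0, 0.0), 0.02),
        MovementSpec("turn_stomach_to_side", (0.00, 0.50, 0.60), 0.5, (0.20, 0.60, 0.60), 0.05, 3.0),
        MovementSpec("turn_side_to_stomach", (0.00, 0.50, 0.60), 0.5, (0.20, 0.60, 0.60), 0.05, 3.0),
    ]
}

# Two-phase seizure model: a rigid tonic phase (sustained postural shift
# with a low-amplitude ~8 Hz tremor) followed by large-amplitude rhythmic
# clonic jerking at ~3 Hz on all axes.
SEIZURE_SPECS: dict[str, MovementSpec] = {
    spec.name: spec
    for spec in [
        MovementSpec("gtcs_tonic", (0.50, 0.30, 0.80), 8.0, (0.15, 0.15, 0.15), 0.05, 5.0),
        MovementSpec("gtcs_clonic", (0.05, 0.05, 0.30), 3.0, (1.80, 1.80, 1.80), 0.20, 25.0),
    ]
}

#: Number of dogs contributing a 9-s block per movement class when the
#: non-seizure reference is assembled (135 blocks -> 1,215 s in total).
TABLE_DOG_COUNTS: dict[str, int] = {
    "walking": 23,
    "standing": 15,
    "shaking": 24,
    "drinking": 7,
    "running": 4,
    "jumping_on_sofa": 3,
    "jumping_off_sofa": 3,
    "lying_on_stomach": 12,
    "lying_on_side": 5,
    "scratching": 4,
    "playing_with_toy": 3,
    "being_stroked": 8,
    "sitting": 14,
    "turn_stomach_to_side": 5,
    "turn_side_to_stomach": 5,
}

ALL_SPECS = {**DAILY_ACTIVITY_SPECS, **SEIZURE_SPECS}

SEIZURE_LABELS = frozenset(SEIZURE_SPECS)


@dataclass(frozen=True)
class Schedule:
    """Ordered, contiguous plan of movement segments covering [0, total)."""

    segments: tuple[tuple[MovementSpec, float], ...]  # (spec, start_s)
    total_duration_s: float
    seed: int = 0

    def __post_init__(self) -> None:
        t = 0.0
        for spec, start in self.segments:
            if abs(start - t) > 1e-9:
                raise ValueError(
                    f"schedule gap/overlap before segment {spec.name!r} "
                    f"(expected start {t}, got {start})"
                )
            t = start + spec.duration_s
        if abs(t - self.total_duration_s) > 1e-9:
            raise ValueError(
                f"segments cover {t} s but total_duration_s is {self.total_duration_s}"
            )


def _segment_signal(
    spec: MovementSpec, rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    if spec.osc_freq_hz >= rate_hz / 2:
        raise ValueError(
            f"oscillation frequency {spec.osc_freq_hz} Hz is at or above "
            f"Nyquist ({rate_hz / 2} Hz)"
        )
    n = int(round(spec.duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    out = np.empty((n, 3))
    for axis in range(3):
        out[:, axis] = (
            spec.base_offset_g[axis]
            + spec.osc_amp_g[axis] * np.sin(2 * np.pi * spec.osc_freq_hz * t + phases[axis])
            + rng.normal(0.0, spec.noise_sd_g, size=n)
        )
    return out


def simulate_segment(
    spec: MovementSpec, rate_hz: float = 50.0, seed: int | np.random.Generator = 0
) -> AccelTrace:
    """Generate one movement segment; identical seeds give identical traces."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return AccelTrace(sampling_rate_hz=rate_hz, samples=_segment_signal(spec, rate_hz, rng))


def simulate_gtcs(
    tonic_s: float = 5.0,
    clonic_s: float = 25.0,
    rate_hz: float = 50.0,
    seed: int | np.random.Generator = 0,
) -> tuple[AccelTrace, list[LabelInterval]]:
    """A labelled two-phase seizure trace: tonic rigidity then clonic jerking.

    Either phase may have zero length (but not both); labels carry only
    the phases present.
    """
    if tonic_s < 0 or clonic_s < 0 or tonic_s + clonic_s < 1.0:
        raise ValueError("tonic_s + clonic_s must be at least 1 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = []
    labels = []
    t = 0.0
    for name, dur in (("gtcs_tonic", tonic_s), ("gtcs_clonic", clonic_s)):
        if dur <= 0:
            continue
        spec = replace(SEIZURE_SPECS[name], duration_s=dur)
        parts.append(_segment_signal(spec, rate_hz, rng))
        labels.append(LabelInterval(name, t, t + dur))
        t += dur
    trace = AccelTrace(sampling_rate_hz=rate_hz, samples=np.vstack(parts))
    return trace, labels


def simulate_day(
    schedule: Schedule, rate_hz: float = 50.0
) -> tuple[AccelTrace, list[LabelInterval]]:
    """Concatenate a schedule's segments into one labelled recording."""
    rng = np.random.default_rng(schedule.seed)
    parts = []
    labels = []
    for spec, start in schedule.segments:
        parts.append(_segment_signal(spec, rate_hz, rng))
        labels.append(LabelInterval(spec.name, start, start + spec.duration_s))
    samples = np.vstack(parts) if parts else np.empty((0, 3))
    trace = AccelTrace(sampling_rate_hz=rate_hz, samples=samples)
    return trace, labels


def rotation_about_axis(axis: str, degrees: float) -> np.ndarray:
    """Rotation matrix about a sensor axis ('x' craniocaudal, 'y' lateral,
    'z' dorsoventral)."""
    return Rotation.from_euler(axis, degrees, degrees=True).as_matrix()


def apply_displacement(
    trace: AccelTrace, rotation: np.ndarray, onset_s: float
) -> AccelTrace:
    """Rotate the sensor frame from *onset_s* onward (harness slippage).

    Samples before onset are unchanged; afterwards each sample vector is
    mapped through the (orthonormal) rotation matrix.  Rotations preserve
    the resultant-force magnitude exactly.
    """
    rot = np.asarray(rotation, dtype=float)
    if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    i0 = int(round(onset_s * trace.sampling_rate_hz))
    i0 = max(0, min(i0, trace.n_samples))
    samples = trace.samples.copy()
    samples[i0:] = samples[i0:] @ rot.T
    return replace(trace, samples=samples)


def reference_collection_schedule(seed: int = 0) -> Schedule:
    """The daily-activity reference collection plan: one 9-s block per dog
    per movement class (135 blocks, 1,215 s in total)."""
    segments = []
    t = 0.0
    for name, n_dogs in TABLE_DOG_COUNTS.items():
        spec = replace(DAILY_ACTIVITY_SPECS[name], duration_s=9.0)
        for _ in range(n_dogs):
            segments.append((spec, t))
            t += 9.0
    return Schedule(segments=tuple(segments), total_duration_s=t, seed=seed)


def day_schedule_with_seizures(
    total_s: float = 1800.0,
    seizure_starts_s: tuple[float, ...] = (),
    tonic_s: float = 5.0,
    clonic_s: float = 25.0,
    seed: int = 0,
) -> Schedule:
    """A contiguous activity schedule with optional embedded seizures.

    Daily-activity segments are drawn (seeded) from the class table and
    trimmed so each seizure begins exactly at its requested start.
    """
    rng = np.random.default_rng(seed)
    names = list(DAILY_ACTIVITY_SPECS)
    seizure_len = tonic_s + clonic_s
    boundaries = sorted(seizure_starts_s)
    for a, b in zip(boundaries, boundaries[1:]):
        if b < a + seizure_len:
            raise ValueError("seizure intervals overlap")
    if boundaries and boundaries[-1] + seizure_len > total_s:
        raise ValueError("seizure extends past the schedule end")
    segments: list[tuple[MovementSpec, float]] = []
    t = 0.0

    def fill_activity(until: float) -> None:
        nonlocal t
        while t < until - 1e-9:
            spec = DAILY_ACTIVITY_SPECS[names[rng.integers(len(names))]]
            dur = min(spec.duration_s, until - t)
            segments.append((replace(spec, duration_s=dur), t))
            t += dur

    for start in boundaries:
        fill_activity(start)
        if tonic_s > 0:
            segments.append((replace(SEIZURE_SPECS["gtcs_tonic"], duration_s=tonic_s), t))
            t += tonic_s
        if clonic_s > 0:
            segments.append((replace(SEIZURE_SPECS["gtcs_clonic"], duration_s=clonic_s), t))
            t += clonic_s
    fill_activity(total_s)
    return Schedule(segments=tuple(segments), total_duration_s=t, seed=seed)


def save_schedule(schedule: Schedule, path: str | Path) -> Path:
    """Write a schedule as JSON ({seed, segments:[{name,duration_s,...}]})."""
    payload = {
        "seed": schedule.seed,
        "segments": [
            {
                "name": spec.name,
                "duration_s": spec.duration_s,
                "base_offset_g": list(spec.base_offset_g),
                "osc_freq_hz": spec.osc_freq_hz,
                "osc_amp_g": list(spec.osc_amp_g),
                "noise_sd_g": spec.noise_sd_g,
            }
            for spec, _ in schedule.segments
        ],
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    return path


def load_schedule(path: str | Path) -> Schedule:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    segments = []
    t = 0.0
    for seg in payload["segments"]:
        spec = MovementSpec(
            name=seg["name"],
            base_offset_g=tuple(seg["base_offset_g"]),
            osc_freq_hz=seg["osc_freq_hz"],
            osc_amp_g=tuple(seg["osc_amp_g"]),
            noise_sd_g=seg["noise_sd_g"],
            duration_s=seg["duration_s"],
        )
        segments.append((spec, t))
        t += spec.duration_s
    return Schedule(segments=tuple(segments), total_duration_s=t, seed=payload.get("seed", 0))
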