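"""Streaming seizure detection over a per-second feature stream.

The detector slides a fixed-length epoch over the feature stream (1-s
stride by default), classifies each epoch with the two-reference rule and
raises a :class:`DetectionEvent` on the rising edge of a run of positive
epochs.  A refractory period suppresses repeat notifications from a single
seizure, and ``min_consecutive_positives`` optionally debounces short
positive bursts (useful when studying shorter epoch lengths, which trade
latency against false alarms).

The incremental path (:class:`StreamingDetector`, fed one second at a
time) is exactly equivalent to batch classification of the whole stream —
:func:`replay_equivalence` asserts this on any recording.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import AGGREGATORS, ClassificationResult, classify_epochs
from .features import FEATURE_COLUMNS, Epoch, make_epochs, per_second_features
from .io import AccelTrace
from .reference import ReferenceModel

__all__ = [
    "DetectorConfig",
    "DetectionEvent",
    "StreamingDetector",
    "detect_stream",
    "replay_equivalence",
    "EquivalenceFailure",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Windowing and debounce settings for the streaming detector.

    epoch_length_s:
        Seconds per classification window (default 9; 3 and 6 supported
        for the epoch-length trade-off study).
    stride_s:
        Window shift per step in seconds (default 1).
    aggregator:
        How per-second distances combine into an epoch distance.
    refractory_s:
        Quiet period after an event during which no further event fires,
        so one seizure raises one notification (default 60 s).
    min_consecutive_positives:
        Positive epochs required before an event fires (default 1: a
        single positive epoch alerts).
    """

    epoch_length_s: int = 9
    stride_s: int = 1
    aggregator: str = "mean"
    refractory_s: int = 60
    min_consecutive_positives: int = 1

    def __post_init__(self) -> None:
        if self.epoch_length_s < 1:
            raise ValueError("epoch_length_s must be >= 1")
        if self.stride_s < 1:
            raise ValueError("stride_s must be >= 1")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")
        if self.min_consecutive_positives < 1:
            raise ValueError("min_consecutive_positives must be >= 1")
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")


@dataclass(frozen=True)
class DetectionEvent:
    """A seizure call: onset of the first positive epoch in the run, the
    epoch whose classification completed the run, and its distances."""

    onset_s: int
    trigger_epoch_start_s: int
    distance_rde: float
    distance_rdne: float


class StreamingDetector:
    """Incremental detector: feed per-second feature rows, collect events.

    Maintains a rolling window of the last ``epoch_length_s`` feature rows;
    whenever a full window aligned to the stride is available it is
    classified, and event/debounce/refractory state advances exactly as in
    the batch pipeline.
    """

    def __init__(
        self, rde: ReferenceModel, rdne: ReferenceModel, config: DetectorConfig
    ) -> None:
        self.rde = rde
        self.rdne = rdne
        self.config = config
        self._window: deque[np.ndarray] = deque(maxlen=config.epoch_length_s)
        self._second = 0
        self._run_length = 0
        self._run_onset: int | None = None
        self._fired_this_run = False
        self._last_event_onset: int | None = None
        self.results: list[ClassificationResult] = []
        self.events: list[DetectionEvent] = []

    def push(self, feature_row: np.ndarray) -> DetectionEvent | None:
        """Feed one per-second feature row; returns an event if one fires."""
        row = np.asarray(feature_row, dtype=float)
        if row.shape != (len(FEATURE_COLUMNS),):
            raise ValueError("feature row must be an 8-vector")
        self._window.append(row)
        self._second += 1
        cfg = self.config
        epoch_start = self._second - cfg.epoch_length_s
        if epoch_start < 0 or epoch_start % cfg.stride_s != 0:
            return None
        epoch = Epoch(epoch_start, np.array(self._window))
        (result,) = classify_epochs([epoch], self.rde, self.rdne, cfg.aggregator)
        self.results.append(result)
        return self._advance(result)

    def _advance(self, result: ClassificationResult) -> DetectionEvent | None:
        cfg = self.config
        if not result.is_seizure:
            self._run_length = 0
            self._run_onset = None
            self._fired_this_run = False
            return None
        if self._run_length == 0:
            self._run_onset = result.epoch_start_s
        self._run_length += 1
        if self._fired_this_run or self._run_length < cfg.min_consecutive_positives:
            return None
        # single decision point per positive run: once the debounce count is
        # reached, either fire or (inside the refractory window) suppress the
        # whole run
        self._fired_this_run = True
        if (
            self._last_event_onset is not None
            and self._run_onset - self._last_event_onset < cfg.refractory_s
        ):
            return None
        event = DetectionEvent(
            onset_s=self._run_onset,
            trigger_epoch_start_s=result.epoch_start_s,
            distance_rde=result.distance_rde,
            distance_rdne=result.distance_rdne,
        )
        self.events.append(event)
        self._last_event_onset = event.onset_s
        return event


def detect_stream(
    features: pd.DataFrame | np.ndarray,
    rde: ReferenceModel,
    rdne: ReferenceModel,
    config: DetectorConfig = DetectorConfig(),
) -> list[DetectionEvent]:
    """Run the detector over a whole feature stream (batch mode).

    A stream shorter than one epoch yields no events.  Batch output is
    identical to pushing the same rows through :class:`StreamingDetector`.
    """
    results = _batch_results(features, rde, rdne, config)
    return _events_from_results(results, config)


def _batch_results(
    features, rde: ReferenceModel, rdne: ReferenceModel, config: DetectorConfig
) -> list[ClassificationResult]:
    epochs = make_epochs(features, config.epoch_length_s, config.stride_s)
    return classify_epochs(epochs, rde, rdne, config.aggregator)


def _events_from_results(
    results: list[ClassificationResult], config: DetectorConfig
) -> list[DetectionEvent]:
    events: list[DetectionEvent] = []
    run_length = 0
    run_onset: int | None = None
    fired = False
    last_onset: int | None = None
    for res in results:
        if not res.is_seizure:
            run_length, run_onset, fired = 0, None, False
            continue
        if run_length == 0:
            run_onset = res.epoch_start_s
        run_length += 1
        if fired or run_length < config.min_consecutive_positives:
            continue
        fired = True
        if (
            last_onset is not None
            and run_onset - last_onset < config.refractory_s
        ):
            continue
        events.append(
            DetectionEvent(
                onset_s=run_onset,
                trigger_epoch_start_s=res.epoch_start_s,
                distance_rde=res.distance_rde,
                distance_rdne=res.distance_rdne,
            )
        )
        last_onset = run_onset
    return events


class EquivalenceFailure(AssertionError):
    """Streaming and batch pipelines diverged."""


def replay_equivalence(
    trace: AccelTrace,
    rde: ReferenceModel,
    rdne: ReferenceModel,
    config: DetectorConfig = DetectorConfig(),
) -> dict:
    """Assert the streaming and batch pipelines agree on *trace*.

    Extracts per-second features once, then classifies them (a) in one
    batch and (b) one second at a time through :class:`StreamingDetector`,
    comparing every ClassificationResult and every event.  Returns a small
    report dict; raises :class:`EquivalenceFailure` naming the first
    differing epoch otherwise.
    """
    feats = per_second_features(trace)
    batch_results = _batch_results(feats, rde, rdne, config)
    batch_events = _events_from_results(batch_results, config)

    stream = StreamingDetector(rde, rdne, config)
    for row in feats[FEATURE_COLUMNS].to_numpy(dtype=float):
        stream.push(row)

    for i, (b, s) in enumerate(zip(batch_results, stream.results)):
        if (
            b.epoch_start_s != s.epoch_start_s
            or b.decision != s.decision
            or abs(b.distance_rde - s.distance_rde) > 1e-12
            or abs(b.distance_rdne - s.distance_rdne) > 1e-12
        ):
            raise EquivalenceFailure(
                f"first divergence at epoch index {i} "
                f"(batch start={b.epoch_start_s}, stream start={s.epoch_start_s})"
            )
    if len(batch_results) != len(stream.results):
        raise EquivalenceFailure(
            f"epoch count mismatch: batch {len(batch_results)}, "
            f"stream {len(stream.results)}"
        )
    if batch_events != stream.events:
        raise EquivalenceFailure("event lists differ between batch and stream")
    return {
        "n_epochs": len(batch_results),
        "n_events": len(batch_events),
        "equivalent": True,
    }
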