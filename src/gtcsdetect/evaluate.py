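"""Event- and epoch-level scoring of detector output against ground truth.

Event scoring matches each detection to at most one true seizure interval
(an event matches when its onset falls within ``tolerance_s`` before the
seizure start through the seizure end); leftovers are false-positive
events or missed seizures.  Epoch scoring builds the 2x2 decision-vs-truth
confusion table, calling an epoch seizure-truth when at least half its
span overlaps a seizure interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassificationResult
from .detector import DetectionEvent
from .io import LabelInterval

__all__ = [
    "EvalReport",
    "DEFAULT_MATCH_TOLERANCE_S",
    "match_events",
    "epoch_confusion",
    "evaluate_detection",
]

#: Seconds before a true seizure onset within which an event still counts
#: as detecting that seizure (the detector can fire slightly early on
#: pre-onset windows that already overlap the seizure).
DEFAULT_MATCH_TOLERANCE_S = 5.0


@dataclass(frozen=True)
class EvalReport:
    """Figures of merit for one monitored recording."""

    true_positives: int
    false_negatives: int
    false_positive_events: int
    sensitivity: float | None  # None when no true seizures exist
    false_positives_per_24h: float
    mean_latency_s: float | None
    epoch_confusion: tuple[tuple[int, int], tuple[int, int]] | None = None
    monitored_s: float = 0.0

    def to_dict(self) -> dict:
        d = {
            "true_positives": self.true_positives,
            "false_negatives": self.false_negatives,
            "false_positive_events": self.false_positive_events,
            "sensitivity": self.sensitivity,
            "false_positives_per_24h": self.false_positives_per_24h,
            "mean_latency_s": self.mean_latency_s,
            "monitored_s": self.monitored_s,
        }
        if self.epoch_confusion is not None:
            d["epoch_confusion"] = [list(r) for r in self.epoch_confusion]
        return d

    def summary(self) -> str:
        sens = "n/a" if self.sensitivity is None else f"{self.sensitivity:.3f}"
        lat = "n/a" if self.mean_latency_s is None else f"{self.mean_latency_s:.1f} s"
        return (
            f"TP={self.true_positives} FN={self.false_negatives} "
            f"FP-events={self.false_positive_events} sensitivity={sens} "
            f"FP/24h={self.false_positives_per_24h:.3f} mean-latency={lat}"
        )


def match_events(
    events: list[DetectionEvent],
    truth: list[LabelInterval],
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
) -> tuple[list[tuple[DetectionEvent, LabelInterval]], list[DetectionEvent], list[LabelInterval]]:
    """Greedy one-to-one event/seizure matching.

    Returns (matched pairs, unmatched events, unmatched seizures).  An
    event is a candidate for a seizure when its onset lies in
    [start - tolerance_s, end]; each seizure takes the earliest candidate
    event.  The result is independent of the input ordering.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be >= 0")
    events = sorted(events, key=lambda e: e.onset_s)
    truth = sorted(truth)
    matched: list[tuple[DetectionEvent, LabelInterval]] = []
    used = [False] * len(events)
    for iv in truth:
        for i, ev in enumerate(events):
            if used[i]:
                continue
            if iv.start_s - tolerance_s <= ev.onset_s <= iv.end_s:
                matched.append((ev, iv))
                used[i] = True
                break
    unmatched_events = [ev for i, ev in enumerate(events) if not used[i]]
    matched_truth = {id(iv) for _, iv in matched}
    unmatched_truth = [iv for iv in truth if id(iv) not in matched_truth]
    return matched, unmatched_events, unmatched_truth


def _seizure_overlap(start: float, end: float, seizures: list[LabelInterval]) -> float:
    return sum(
        max(0.0, min(end, iv.end_s) - max(start, iv.start_s)) for iv in seizures
    )


def epoch_confusion(
    results: list[ClassificationResult],
    truth: list[LabelInterval],
    epoch_length_s: int = 9,
    seizure_labels: frozenset[str] | set[str] | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 table rows = truth (seizure, non-seizure), cols = decision.

    An epoch counts as seizure-truth when at least half its span overlaps
    a seizure-labelled interval.  Cells sum to the number of epochs.
    """
    from .simulate import SEIZURE_LABELS  # default truth labels

    labels = SEIZURE_LABELS if seizure_labels is None else set(seizure_labels)
    seizures = [iv for iv in truth if iv.label in labels]
    tp = fn = fp = tn = 0
    for res in results:
        start = res.epoch_start_s
        overlap = _seizure_overlap(start, start + epoch_length_s, seizures)
        is_seizure_truth = overlap >= epoch_length_s / 2.0
        if is_seizure_truth:
            if res.is_seizure:
                tp += 1
            else:
                fn += 1
        else:
            if res.is_seizure:
                fp += 1
            else:
                tn += 1
    return ((tp, fn), (fp, tn))


def evaluate_detection(
    events: list[DetectionEvent],
    truth: list[LabelInterval],
    monitored_s: float,
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
    results: list[ClassificationResult] | None = None,
    epoch_length_s: int = 9,
    seizure_labels: frozenset[str] | set[str] | None = None,
) -> EvalReport:
    """Score a detector run: event-level sensitivity, false-alarm rate per
    24 h, mean detection latency, and (optionally) the epoch confusion."""
    from .simulate import SEIZURE_LABELS

    labels = SEIZURE_LABELS if seizure_labels is None else set(seizure_labels)
    seizure_truth = _merge_contiguous(
        [iv for iv in sorted(truth) if iv.label in labels]
    )
    matched, fp_events, missed = match_events(events, seizure_truth, tolerance_s)
    tp = len(matched)
    fn = len(missed)
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    fp_rate = (
        len(fp_events) / (monitored_s / 86400.0) if monitored_s > 0 else 0.0
    )
    latencies = [ev.onset_s - iv.start_s for ev, iv in matched]
    mean_latency = float(np.mean(latencies)) if latencies else None
    confusion = (
        epoch_confusion(results, truth, epoch_length_s, labels)
        if results is not None
        else None
    )
    return EvalReport(
        true_positives=tp,
        false_negatives=fn,
        false_positive_events=len(fp_events),
        sensitivity=sensitivity,
        false_positives_per_24h=fp_rate,
        mean_latency_s=mean_latency,
        epoch_confusion=confusion,
        monitored_s=monitored_s,
    )


def _merge_contiguous(sorted_intervals: list[LabelInterval]) -> list[LabelInterval]:
    """Merge touching/overlapping seizure-phase intervals into whole
    seizures (tonic + clonic phases become one event target)."""
    merged: list[LabelInterval] = []
    for iv in sorted_intervals:
        if merged and iv.start_s <= merged[-1].end_s + 1e-9:
            prev = merged.pop()
            merged.append(
                LabelInterval("seizure", prev.start_s, max(prev.end_s, iv.end_s))
            )
        else:
            merged.append(LabelInterval("seizure", iv.start_s, iv.end_s))
    return merged
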