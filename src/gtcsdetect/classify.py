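"""Two-reference Mahalanobis-distance classification of feature epochs.

An epoch is assigned to the seizure class exactly when its distance to the
seizure reference is strictly shorter than its distance to the
daily-activity reference; ties go to non-seizure (favouring specificity).

The per-second distance is reported in the Mahalanobis-Taguchi convention,
d_t = sqrt((x-mu)^T Sigma^-1 (x-mu) / k) with k = 8 features, so rows
drawn from the reference itself score near 1.  An epoch's distance is an
aggregate (mean by default) of its per-second distances.  The decision is
invariant to any monotone transform applied to both sides, so only the
comparison direction — not the reported scale — is load-bearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve

from .features import Epoch
from .reference import ReferenceModel

__all__ = [
    "ClassificationResult",
    "AGGREGATORS",
    "mahalanobis_sq",
    "epoch_distance",
    "classify_epoch",
    "classify_epochs",
]

AGGREGATORS = {
    "mean": np.mean,
    "median": np.median,
    "max": np.max,
}


@dataclass(frozen=True)
class ClassificationResult:
    """Decision for one epoch, with its distance evidence."""

    epoch_start_s: int
    distance_rde: float
    distance_rdne: float
    decision: str  # "seizure" | "non_seizure"
    aggregator_used: str = "mean"

    @property
    def is_seizure(self) -> bool:
        return self.decision == "seizure"


def mahalanobis_sq(x: np.ndarray, model: ReferenceModel) -> float:
    """Squared Mahalanobis distance (x-mu)^T Sigma^-1 (x-mu).

    Solved through the model's cached Cholesky factorization rather than
    an explicit matrix inverse.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != model.mean.shape:
        raise ValueError(
            f"feature vector has shape {x.shape}, model expects {model.mean.shape}"
        )
    diff = x - model.mean
    solved = cho_solve(model.cholesky(), diff)
    value = float(diff @ solved)
    # guard tiny negative round-off on near-zero distances
    return max(value, 0.0)


def _row_distances(values: np.ndarray, model: ReferenceModel) -> np.ndarray:
    diffs = values - model.mean
    solved = cho_solve(model.cholesky(), diffs.T)
    sq = np.maximum(np.einsum("ij,ji->i", diffs, solved), 0.0)
    return np.sqrt(sq / model.dim)


def epoch_distance(
    epoch: Epoch, model: ReferenceModel, aggregator: str = "mean"
) -> float:
    """Aggregate of per-second scaled distances d_t = sqrt(D_t^2 / k)."""
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    if epoch.values.shape[1] != model.dim:
        raise ValueError("epoch rows incompatible with model dimension")
    return float(AGGREGATORS[aggregator](_row_distances(epoch.values, model)))


def decide(distance_rde: float, distance_rdne: float) -> str:
    """Shorter-distance rule: seizure iff strictly closer to the seizure
    reference; an exact tie is non-seizure."""
    return "seizure" if distance_rde < distance_rdne else "non_seizure"


def classify_epoch(
    epoch: Epoch,
    rde: ReferenceModel,
    rdne: ReferenceModel,
    aggregator: str = "mean",
) -> ClassificationResult:
    """Classify one epoch against the seizure and non-seizure references."""
    if rde.label == rdne.label:
        raise ValueError(
            f"the two reference models must carry distinct labels, both are {rde.label!r}"
        )
    d_rde = epoch_distance(epoch, rde, aggregator)
    d_rdne = epoch_distance(epoch, rdne, aggregator)
    return ClassificationResult(
        epoch_start_s=epoch.start_second,
        distance_rde=d_rde,
        distance_rdne=d_rdne,
        decision=decide(d_rde, d_rdne),
        aggregator_used=aggregator,
    )


def classify_epochs(
    epochs: list[Epoch],
    rde: ReferenceModel,
    rdne: ReferenceModel,
    aggregator: str = "mean",
) -> list[ClassificationResult]:
    """Batch classification of a list of epochs (order preserved)."""
    return [classify_epoch(e, rde, rdne, aggregator) for e in epochs]
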