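"""Reference models: per-class feature mean and variance-covariance matrix.

The classifier compares each epoch against two references — one built from
seizure (tonic-clonic phase) feature rows, one from daily-activity rows.
A reference is simply the column mean and the population variance-
covariance matrix of its per-second 8-parameter feature rows, with an
optional ridge term to guarantee positive definiteness.  At least nine
rows are required: with 8 features, nine observations is the generic
invertibility threshold for the covariance matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, eigh

from .features import FEATURE_COLUMNS, InsufficientDataError

__all__ = [
    "MIN_REFERENCE_ROWS",
    "SEIZURE",
    "NON_SEIZURE",
    "ReferenceModel",
    "ReferenceFormatError",
    "build_reference",
    "regularize_covariance",
    "save_reference",
    "load_reference",
]

#: Minimum feature rows per reference: the variance-covariance matrix of
#: 8 features needs at least 9 observations to be invertible.
MIN_REFERENCE_ROWS = 9

SEIZURE = "seizure"
NON_SEIZURE = "non_seizure"

SCHEMA_VERSION = 1

# Relative threshold below which the smallest eigenvalue counts as
# ill-conditioned, and the absolute ridge floor for a zero-trace matrix.
_COND_EPS = 1e-8
_ABS_RIDGE_FLOOR = 1e-12


class ReferenceFormatError(ValueError):
    """Reference JSON file is malformed or from an unknown schema."""


@dataclass(frozen=True, eq=False)
class ReferenceModel:
    """A class label with the mean and covariance of its feature rows."""

    label: str
    mean: np.ndarray
    covariance: np.ndarray
    n_rows: int
    ridge_used: float = 0.0
    source_manifest: tuple[str, ...] = ()
    _cho: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        k = mean.shape[0]
        if mean.ndim != 1:
            raise ValueError("mean must be a vector")
        if cov.shape != (k, k):
            raise ValueError(f"covariance must be {k}x{k}")
        if not np.allclose(cov, cov.T, rtol=1e-10, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if self.n_rows < MIN_REFERENCE_ROWS:
            raise ValueError(
                f"reference needs at least {MIN_REFERENCE_ROWS} feature rows "
                f"to determine an invertible covariance, got {self.n_rows}"
            )
        mean.setflags(write=False)
        cov.setflags(write=False)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        try:
            factor = cho_factor(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance is not positive definite") from exc
        object.__setattr__(self, "_cho", factor)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def cholesky(self) -> tuple:
        """Cached Cholesky factorization used by the distance solver."""
        return self._cho


def regularize_covariance(cov: np.ndarray, ridge: float) -> np.ndarray:
    """Add a ridge lambda*I when the matrix is (near-)singular.

    lambda = ridge * trace(cov)/dim when the smallest eigenvalue falls at
    or below ``1e-8 * trace/dim``; for a zero-trace (all-constant-rows)
    matrix lambda is floored at an absolute 1e-12 so the degenerate case
    remains usable.  A well-conditioned matrix is returned unchanged.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, rtol=1e-10, atol=1e-12):
        raise ValueError("covariance must be symmetric")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    k = cov.shape[0]
    scale = np.trace(cov) / k
    smallest = eigh(cov, eigvals_only=True, subset_by_index=(0, 0))[0]
    if smallest > _COND_EPS * scale and smallest > 0:
        return cov
    lam = ridge * scale
    if lam <= 0.0:
        lam = max(lam, _ABS_RIDGE_FLOOR)
    return cov + lam * np.eye(k)


def build_reference(
    rows,
    label: str,
    ridge: float = 1e-6,
    source_manifest: tuple[str, ...] = (),
) -> ReferenceModel:
    """Build a reference model from per-second feature rows.

    ``rows`` is an (n, 8) array or a feature DataFrame; n must be >= 9.
    The covariance is the population (divide-by-n) form, regularized via
    :func:`regularize_covariance`.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows[FEATURE_COLUMNS].to_numpy(dtype=float)
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2:
        raise ValueError("rows must be a 2-D array of feature vectors")
    if arr.shape[0] < MIN_REFERENCE_ROWS:
        raise InsufficientDataError(
            f"reference {label!r} needs at least {MIN_REFERENCE_ROWS} rows "
            f"(got {arr.shape[0]}): fewer cannot determine the "
            "variance-covariance matrix"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature rows contain non-finite values")
    mean = arr.mean(axis=0)
    centered = arr - mean
    cov = centered.T @ centered / arr.shape[0]
    cov = (cov + cov.T) / 2.0
    reg = regularize_covariance(cov, ridge)
    ridge_used = float(reg[0, 0] - cov[0, 0])
    return ReferenceModel(
        label=label,
        mean=mean,
        covariance=reg,
        n_rows=arr.shape[0],
        ridge_used=ridge_used,
        source_manifest=tuple(source_manifest),
    )


def save_reference(model: ReferenceModel, path: str | Path) -> Path:
    """Persist a model as schema-versioned JSON with full float precision."""
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "label": model.label,
        "mean": model.mean.tolist(),
        "covariance": model.covariance.tolist(),
        "n_rows": model.n_rows,
        "ridge_used": model.ridge_used,
        "source_manifest": list(model.source_manifest),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    return path


def load_reference(path: str | Path) -> ReferenceModel:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ReferenceFormatError(
            f"{path}: unsupported reference schema version {version!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    required = {"label", "mean", "covariance", "n_rows"}
    missing = required - payload.keys()
    if missing:
        raise ReferenceFormatError(f"{path}: missing fields {sorted(missing)}")
    return ReferenceModel(
        label=payload["label"],
        mean=np.asarray(payload["mean"], dtype=float),
        covariance=np.asarray(payload["covariance"], dtype=float),
        n_rows=int(payload["n_rows"]),
        ridge_used=float(payload.get("ridge_used", 0.0)),
        source_manifest=tuple(payload.get("source_manifest", ())),
    )
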