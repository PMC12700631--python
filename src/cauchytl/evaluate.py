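"""Prediction metrics: empirical coverage, reliability curves, RMSE, AUC."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .predict import PredictionSet, binary_prediction_set

__all__ = ["CoverageReport", "empirical_coverage", "reliability_curve", "rmse", "auc"]


@dataclass(frozen=True)
class CoverageReport:
    """Empirical coverage on a grid of nominal levels."""

    nominal_levels: np.ndarray
    empirical_coverage: np.ndarray
    n_test: int

    def __post_init__(self) -> None:
        if len(self.nominal_levels) != len(self.empirical_coverage):
            raise ValueError("levels and coverage vectors must align")


def empirical_coverage(sets: Sequence[PredictionSet], truths: np.ndarray) -> float:
    """Fraction of truths contained in their prediction set.

    Interval containment is closed (a truth on an endpoint counts as
    covered); binary containment is label-set membership.
    """
    truths = np.asarray(truths, dtype=float).reshape(-1)
    if len(sets) != len(truths):
        raise ValueError("sets and truths have mismatched lengths")
    hits = sum(s.contains(t) for s, t in zip(sets, truths))
    return hits / len(truths)


def reliability_curve(
    samples,
    truths: np.ndarray,
    levels: Sequence[float],
    kind: Optional[str] = None,
) -> CoverageReport:
    """Empirical coverage at each nominal level, reusing one predictive
    sample per observation (quantiles re-cut per level).

    ``samples`` is either an (n, k) matrix of continuous predictive draws
    (one row per observation) or a length-n vector of binary predictive
    success probabilities; ``kind`` ("continuous"/"binary") disambiguates
    and defaults from the dimensionality.
    """
    truths = np.asarray(truths, dtype=float).reshape(-1)
    levels = np.asarray(list(levels), dtype=float)
    if np.any(levels <= 0.0) or np.any(levels >= 1.0):
        raise ValueError("nominal levels must lie strictly inside (0, 1)")
    samples = np.asarray(samples, dtype=float)
    if kind is None:
        kind = "continuous" if samples.ndim == 2 else "binary"

    coverage = np.empty(levels.size)
    if kind == "continuous":
        if samples.shape[0] != truths.size:
            raise ValueError("one row of draws per observation is required")
        for j, level in enumerate(levels):
            alpha = 1.0 - level
            lo = np.quantile(samples, alpha / 2.0, axis=1)
            hi = np.quantile(samples, 1.0 - alpha / 2.0, axis=1)
            coverage[j] = np.mean((truths >= lo) & (truths <= hi))
    elif kind == "binary":
        p = samples.reshape(-1)
        if p.size != truths.size:
            raise ValueError("one p_tilde per observation is required")
        for j, level in enumerate(levels):
            sets = [binary_prediction_set(pi, 1.0 - level) for pi in p]
            coverage[j] = empirical_coverage(sets, truths)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return CoverageReport(
        nominal_levels=levels, empirical_coverage=coverage, n_test=truths.size
    )


def rmse(point_preds: np.ndarray, truths: np.ndarray) -> float:
    """Root mean squared prediction error."""
    point_preds = np.asarray(point_preds, dtype=float).reshape(-1)
    truths = np.asarray(truths, dtype=float).reshape(-1)
    if point_preds.size != truths.size:
        raise ValueError("predictions and truths have mismatched lengths")
    return float(np.sqrt(np.mean((point_preds - truths) ** 2)))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=float).reshape(-1)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).reshape(-1)))
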