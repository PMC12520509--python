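"""Classification metrics for imbalanced binary decoding.

The Matthews correlation coefficient (MCC) is the primary performance
measure throughout the package: it is the correlation between true and
predicted binary labels computed from the confusion matrix, lives in
[-1, 1], equals 0 for chance-level or single-class predictors, and is
robust to the ~1:4 class imbalance of one-of-five category labels.

Informedness (sensitivity + specificity - 1) and Markedness
(precision + NPV - 1) are reported alongside; on any confusion matrix
with all four marginals nonzero, MCC**2 == informedness * markedness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "mcc",
    "informedness",
    "markedness",
    "mcc_null_distribution",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (all nonnegative)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from two binary label vectors."""
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have identical shapes")
    if t.size == 0:
        raise ValueError("empty label vectors")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.

    Convention: if any factor of the denominator is zero (a predictor or
    label set collapsed onto a single class), the score is defined as 0 —
    such predictors carry no information about the labels.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _safe_ratio(num: float, denom: float) -> float:
    # Degenerate marginal -> the term contributes 0 (logged convention;
    # keeps the metric defined for single-class predictors).
    return num / denom if denom > 0 else 0.0


def informedness(c: ConfusionCounts) -> float:
    """Sensitivity + specificity - 1 (Youden's J), degenerate terms -> 0."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    return _safe_ratio(c.tp, c.tp + c.fn) + _safe_ratio(c.tn, c.tn + c.fp) - 1.0


def markedness(c: ConfusionCounts) -> float:
    """Precision + negative predictive value - 1, degenerate terms -> 0."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    return _safe_ratio(c.tp, c.tp + c.fp) + _safe_ratio(c.tn, c.tn + c.fn) - 1.0


def mcc_null_distribution(
    n_trials: int,
    positive_fraction: float = 0.5,
    n_draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """MCC distribution of label-independent random predictors.

    Each draw pairs a label vector with exactly
    ``round(n_trials * positive_fraction)`` positives (in random order)
    with predictions drawn independently as fair coin flips; the MCC of
    each pairing is computed with the degenerate-denominator convention.
    The mean converges to 0 (chance level).

    Returns a dict with ``mean``, ``std`` and the raw ``samples``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_trials * positive_fraction))
    base = np.zeros(n_trials, dtype=int)
    base[:n_pos] = 1
    samples = np.empty(n_draws)
    for i in range(n_draws):
        labels = rng.permutation(base)
        preds = rng.integers(0, 2, size=n_trials)
        samples[i] = mcc(confusion_counts(labels, preds))
    return {
        "mean": float(samples.mean()),
        "std": float(samples.std()),
        "samples": samples,
    }
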