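"""Classification metrics: confusion counts, ACC/SEN/SPE, ROC and AUC."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["EvalReport", "confusion_metrics", "roc_auc"]


@dataclass
class EvalReport:
    """Confusion counts and derived metrics of one evaluation.

    A metric whose denominator is empty (e.g. sensitivity with no positive
    labels) is ``None`` — explicitly undefined, never silently zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    roc_points: Optional[list[tuple[float, float]]] = None  # (FPR, TPR)
    auc: Optional[float] = None
    dataset_fingerprint: Optional[str] = None
    config: dict = field(default_factory=dict)

    def validate(self) -> None:
        n = self.tp + self.tn + self.fp + self.fn
        if n > 0 and self.accuracy is not None:
            assert abs(self.accuracy - (self.tp + self.tn) / n) < 1e-12
        if self.tp + self.fn > 0 and self.sensitivity is not None:
            assert abs(self.sensitivity - self.tp / (self.tp + self.fn)) < 1e-12
        if self.tn + self.fp > 0 and self.specificity is not None:
            assert abs(self.specificity - self.tn / (self.tn + self.fp)) < 1e-12
        if self.auc is not None:
            assert 0.0 <= self.auc <= 1.0
        if self.roc_points:
            fpr = [p[0] for p in self.roc_points]
            tpr = [p[1] for p in self.roc_points]
            assert all(b >= a - 1e-12 for a, b in zip(fpr, fpr[1:]))
            assert all(b >= a - 1e-12 for a, b in zip(tpr, tpr[1:]))


def confusion_metrics(predictions, labels) -> EvalReport:
    """Binary confusion counts and ACC/SEN/SPE from 0/1 predictions."""
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {y.shape} labels")
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = tp + fp + tn + fn
    report = EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n if n else None,
        sensitivity=tp / (tp + fn) if (tp + fn) else None,
        specificity=tn / (tn + fp) if (tn + fp) else None,
    )
    report.validate()
    return report


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and the AUC.

    The AUC equals the normalized Mann-Whitney U statistic (probability that
    a random positive outscores a random negative, ties at half credit) and
    is invariant under strictly monotone score transforms.

    Raises
    ------
    ValueError
        If only one class is present (the curve is undefined).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC/AUC undefined with a single class present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, auc
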