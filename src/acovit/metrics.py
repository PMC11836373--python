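"""Confusion-matrix metrics: accuracy, macro P/R/F1, minority-class recall.

Rows of the confusion matrix are true classes, columns are predictions.
Per-class precision is diagonal over column sum and recall diagonal over
row sum, both 0 when the denominator is 0; F1 is their harmonic mean (0
when both are 0); macro averages are unweighted class means. The
minority-class accuracy is the recall of the smallest-support class (ties
resolved to the lowest class index) — the figure of merit for rare-disease
sensitivity under imbalance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "confusion_matrix",
    "macro_metrics",
    "minority_class_accuracy",
    "MetricsReport",
]


@dataclass
class MetricsReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class_recall: np.ndarray
    minority_class_accuracy: float | None = None
    absent_classes: tuple[int, ...] = ()  # classes with zero true support
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "minority_class_accuracy": self.minority_class_accuracy,
        }
        for c, r in enumerate(self.per_class_recall):
            d[f"recall_class_{c}"] = float(r)
        d.update(self.extra)
        return d

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "value"])
            for k, v in self.to_dict().items():
                w.writerow([k, v])


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """counts[t][p] = number of samples with true class t predicted as p."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    if y_true.size == 0:
        return cm
    if y_true.min() < 0 or y_true.max() >= n_classes or \
       y_pred.min() < 0 or y_pred.max() >= n_classes:
        raise ValueError(f"labels out of range for {n_classes} classes")
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def macro_metrics(cm: np.ndarray) -> MetricsReport:
    """Accuracy and macro-averaged precision/recall/F1 from a confusion matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)
    both = precision + recall
    f1 = np.divide(2 * precision * recall, both,
                   out=np.zeros_like(diag), where=both > 0)
    absent = tuple(int(c) for c in np.flatnonzero(row == 0))
    return MetricsReport(
        accuracy=float(diag.sum() / total),
        precision_macro=float(precision.mean()),
        recall_macro=float(recall.mean()),
        f1_macro=float(f1.mean()),
        per_class_recall=recall,
        absent_classes=absent,
    )


def minority_class_accuracy(cm: np.ndarray, support: np.ndarray) -> float:
    """Recall of the smallest-support class (ties: lowest class index).

    ``support`` normally equals the row sums of ``cm`` but may come from the
    original (pre-resampling) counts when the evaluated split was balanced
    artificially.
    """
    cm = np.asarray(cm, dtype=np.float64)
    support = np.asarray(support)
    if support.sum() != cm.sum():
        raise ValueError("support must sum to the confusion-matrix total")
    c = int(np.argmin(support))
    row = cm[c].sum()
    return float(cm[c, c] / row) if row > 0 else 0.0
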