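"""Classification metrics: confusion matrix, accuracy / precision / recall /
F1 via per-class one-vs-rest reduction with macro averaging, and per-class +
averaged ROC curves.

Class codes are fixed: 0 walking, 1 ascending stairs, 2 descending stairs,
3 squatting. The headline metrics follow the binary definitions
accuracy = (TP+TN)/(TP+TN+FP+FN), recall = TP/(TP+FN),
precision = TP/(TP+FP), F1 = 2PR/(P+R), reduced one class versus the rest and
macro-averaged; per-class values are always kept alongside so either
convention is inspectable. Multi-class accuracy is trace/total.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

N_CLASSES = 4

__all__ = ["ConfusionMatrix", "MetricReport", "ROCSet", "confusion", "metrics", "roc"]

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray       # (K, K); rows true class, columns predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    averaging: str = "macro"

    def as_percent(self) -> dict[str, float]:
        """Headline metrics on the percentage scale, 2 decimals."""
        return {k: round(100 * getattr(self, k), 2)
                for k in ("accuracy", "precision", "recall", "f1")}

    def to_json(self) -> str:
        return json.dumps({
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "averaging": self.averaging,
            "per_class": {str(k): v for k, v in self.per_class.items()},
        }, indent=2, sort_keys=True)


@dataclass
class ROCSet:
    per_class_curves: dict[int, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    mean_curve: tuple[np.ndarray, np.ndarray]
    auc_per_class: dict[int, float]
    mean_auc: float


def confusion(y_true, y_pred, n_classes: int = N_CLASSES) -> ConfusionMatrix:
    """counts[t][p] = number of samples with true class t predicted as p."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains codes outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Per-class one-vs-rest TP/TN/FP/FN reduction, then macro averages.

    A class never predicted positive gets precision 0 with a warning rather
    than NaN.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = counts.shape[0]
    per_class: dict[int, dict[str, float]] = {}
    for c in range(k):
        tp = counts[c, c]
        fn = counts[c].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fp == 0:
            log.warning("class %d has no predicted positives; precision set to 0", c)
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[c] = {
            "tp": int(tp), "tn": int(tn), "fp": int(fp), "fn": int(fn),
            "accuracy": (tp + tn) / total, "precision": prec,
            "recall": rec, "f1": f1,
        }
    return MetricReport(
        accuracy=float(np.trace(counts)) / total,
        precision=float(np.mean([per_class[c]["precision"] for c in range(k)])),
        recall=float(np.mean([per_class[c]["recall"] for c in range(k)])),
        f1=float(np.mean([per_class[c]["f1"] for c in range(k)])),
        per_class=per_class,
    )


def roc(probs: np.ndarray, y_true, n_grid: int = 101) -> ROCSet:
    """One-vs-rest staircase ROC per class, plus a vertically averaged mean
    curve on a shared false-positive-rate grid.

    Per-class AUC is the trapezoidal area; the mean AUC is the unweighted mean
    of per-class AUCs. A class absent from ``y_true`` is skipped with a
    warning and excluded from the averages.
    """
    probs = np.asarray(probs, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if probs.ndim != 2 or probs.shape[0] != y_true.size:
        raise ValueError("probs must be (n_samples, n_classes) matching y_true")
    if probs.shape[0] < 2:
        raise ValueError("need at least 2 samples for an ROC curve")
    row_sums = probs.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    grid = np.linspace(0.0, 1.0, n_grid)
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    aucs: dict[int, float] = {}
    mean_tprs = []
    for c in range(probs.shape[1]):
        pos = y_true == c
        if not pos.any():
            log.warning("class %d absent from y_true; excluded from ROC averaging", c)
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), probs[:, c], drop_intermediate=False)
        curves[c] = (fpr, tpr)
        aucs[c] = float(np.trapezoid(tpr, fpr))
        mean_tprs.append(np.interp(grid, fpr, tpr))
    if not curves:
        raise ValueError("no class present in y_true")
    mean_tpr = np.mean(mean_tprs, axis=0)
    mean_tpr[0] = 0.0
    return ROCSet(per_class_curves=curves, mean_curve=(grid, mean_tpr),
                  auc_per_class=aucs, mean_auc=float(np.mean(list(aucs.values()))))
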