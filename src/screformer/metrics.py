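"""Classification evaluation: confusion matrix, accuracy, macro-F1, one-vs-rest AUC.

Conventions: confusion rows are true classes, columns are predicted
classes; accuracy is trace over total; macro-F1 is the unweighted mean of
per-class F1 with an undefined class contributing 0; AUC is the per-class
one-vs-rest area under the ROC curve, computed as the tie-aware rank
statistic (each positive-negative pair scores 1 if the positive ranks
higher, 1/2 on a tie).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["MetricsReport", "confusion_matrix", "accuracy", "macro_f1",
           "ovr_auc", "roc_points", "evaluate"]


def confusion_matrix(true_labels, predicted_labels, C: int) -> np.ndarray:
    """C x C counts; entry (a, b) = cells of true class a predicted as b."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if t.size and (t.min() < 0 or t.max() >= C or p.min() < 0 or p.max() >= C):
        raise ValueError(f"label index out of range [0, {C})")
    cm = np.zeros((C, C), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def accuracy(confusion: np.ndarray) -> float:
    cm = np.asarray(confusion)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def macro_f1(confusion: np.ndarray) -> float:
    """Unweighted mean of per-class F1 = 2PR/(P+R); P+R = 0 contributes 0."""
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    tp = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    if np.any((row == 0) & (col == 0)):
        warnings.warn("class with no members and no predictions; F1 counted as 0",
                      stacklevel=2)
    return float(f1.mean())


def ovr_auc(true_labels, class_scores) -> np.ndarray:
    """One-vs-rest AUC per class from per-class scores (n, C).

    Equals the normalized Mann-Whitney U statistic with ties worth 1/2. A
    class absent from ``true_labels`` (or covering all of them) has no
    positive-negative pairs; its AUC is reported as NaN with a warning.
    """
    t = np.asarray(true_labels, dtype=np.int64)
    s = np.atleast_2d(np.asarray(class_scores, dtype=np.float64))
    if s.shape[0] != t.size:
        raise ValueError("scores do not align with labels")
    C = s.shape[1]
    out = np.full(C, np.nan)
    for c in range(C):
        pos = t == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} has no positive-negative pairs; AUC undefined",
                          stacklevel=2)
            continue
        out[c] = roc_auc_score(pos.astype(int), s[:, c])
    return out


def roc_points(true_labels, class_scores) -> list[dict]:
    """Per-class one-vs-rest ROC curve points (for plotting parity)."""
    t = np.asarray(true_labels, dtype=np.int64)
    s = np.atleast_2d(np.asarray(class_scores, dtype=np.float64))
    curves = []
    for c in range(s.shape[1]):
        pos = (t == c).astype(int)
        if 0 < pos.sum() < len(pos):
            fpr, tpr, thr = roc_curve(pos, s[:, c])
            curves.append({"class": c, "fpr": fpr.tolist(), "tpr": tpr.tolist()})
        else:
            curves.append({"class": c, "fpr": [], "tpr": []})
    return curves


@dataclass
class MetricsReport:
    """Confusion matrix plus the summary battery."""

    confusion: np.ndarray
    accuracy: float
    macro_f1: float
    per_class_auc: np.ndarray
    roc: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class_auc": [None if np.isnan(a) else float(a) for a in self.per_class_auc],
            "roc": self.roc,
        }


def evaluate(true_labels, predicted_labels, class_scores=None, C: int | None = None,
             with_roc: bool = False) -> MetricsReport:
    """Full evaluation battery from integer label vectors (+ optional scores)."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if C is None:
        C = int(max(t.max(), p.max())) + 1
    cm = confusion_matrix(t, p, C)
    if class_scores is not None:
        auc = ovr_auc(t, class_scores)
        roc = roc_points(t, class_scores) if with_roc else []
    else:
        auc = np.full(C, np.nan)
        roc = []
    return MetricsReport(cm, accuracy(cm), macro_f1(cm), auc, roc)
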