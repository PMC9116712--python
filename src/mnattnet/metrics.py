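"""Evaluation suite: confusion matrix, precision/recall/F1, sensitivity/
specificity, ROC-AUC and average precision.

Conventions (all logged in EvalReport):
* predicted positive iff score >= threshold (default 0.5);
* precision = 0 when TP+FP = 0, F1 = 0 when precision+recall = 0;
* ROC-AUC by the trapezoidal rule over tie-grouped thresholds, equal to the
  Mann-Whitney pairwise-concordance probability with ties counted 1/2;
* AP is the step-wise (non-interpolated) sum over the precision-recall
  curve in decreasing-score order, tied scores grouped at one threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "EvalReport", "confusion", "precision_recall_f1",
           "sensitivity_specificity", "roc_auc", "average_precision", "evaluate"]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_table(self) -> str:
        """Row/column layout: rows = actual class, columns = predicted class."""
        rows = [("Actual class", "Pred. with MN", "Pred. without MN"),
                ("With micronuclei", str(self.tp), str(self.fn)),
                ("Without micronuclei", str(self.fp), str(self.tn))]
        widths = [max(len(r[i]) for r in rows) for i in range(3)]
        return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths))
                         for r in rows)


@dataclass
class EvalReport:
    """Threshold-dependent counts plus ranking metrics, all in [0, 1]."""

    threshold: float
    cm: ConfusionMatrix
    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    auc: float
    ap: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _check_pair(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim != 1 or scores.shape != labels.shape:
        raise ValueError(f"scores and labels must be equal-length 1-D arrays, "
                         f"got {scores.shape} and {labels.shape}")
    if scores.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels.astype(np.int64)


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionMatrix:
    """Threshold scores (predicted positive iff score >= threshold)."""
    scores, labels = _check_pair(scores, labels)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(tp=int((pred & pos).sum()),
                           fp=int((pred & ~pos).sum()),
                           fn=int((~pred & pos).sum()),
                           tn=int((~pred & ~pos).sum()))


def precision_recall_f1(cm: ConfusionMatrix) -> tuple[float, float, float]:
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def sensitivity_specificity(cm: ConfusionMatrix) -> tuple[float, float]:
    sen = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    spe = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    return sen, spe


def _ranked_counts(scores, labels):
    """Cumulative TP/FP at each distinct score, in decreasing-score order."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    last = np.r_[s[1:] != s[:-1], True]  # last index of each tie group
    return tp[last], fp[last]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoid over all thresholds)."""
    scores, labels = _check_pair(scores, labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    tp, fp = _ranked_counts(scores, labels)
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return float(np.trapezoid(tpr, fpr))


def average_precision(scores, labels) -> float:
    """Step-wise AP: sum of (R_k - R_{k-1}) * P_k in decreasing-score order."""
    scores, labels = _check_pair(scores, labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("average_precision requires at least one positive")
    tp, fp = _ranked_counts(scores, labels)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    d_recall = np.diff(np.r_[0.0, recall])
    return float((d_recall * precision).sum())


def evaluate(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full report at a stated threshold; AUC/AP are threshold-free."""
    cm = confusion(scores, labels, threshold)
    precision, recall, f1 = precision_recall_f1(cm)
    sen, spe = sensitivity_specificity(cm)
    return EvalReport(threshold=threshold, cm=cm, precision=precision,
                      recall=recall, f1=f1, sensitivity=sen, specificity=spe,
                      auc=roc_auc(scores, labels),
                      ap=average_precision(scores, labels))
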