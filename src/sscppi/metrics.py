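"""Binary-classification performance indices for PPI prediction.

All the usual indices over a thresholded confusion matrix — accuracy,
sensitivity, specificity, precision, F measure (F1), and the Matthews
correlation coefficient — plus binary cross-entropy loss, ROC/PR curves and
their trapezoidal areas.  Classification is positive iff score > threshold
(strictly), with 0.5 the default decision threshold.

Zero-denominator metrics are reported as 0 together with an entry in
``MetricsReport.flags`` naming the undefined quantity, so degenerate inputs
never fail silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from sklearn import metrics as _skm

__all__ = ["MetricsReport", "compute_metrics", "roc_curve", "pr_curve", "bce_loss"]


@dataclass
class MetricsReport:
    loss: float
    acc: float
    sen: float
    spe: float
    pre: float
    f_measure: float
    mcc: float
    auroc: float
    auprc: float
    confusion: Tuple[int, int, int, int]  # (TP, FP, TN, FN)
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "loss": self.loss,
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "pre": self.pre,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
            "flags": ";".join(self.flags),
        }


def _ratio(num: float, den: float, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(f"{name}_undefined")
        return 0.0
    return num / den


def bce_loss(labels: Sequence[int], scores: Sequence[float], eps: float = 1e-7) -> float:
    """Mean binary cross-entropy of probability scores against 0/1 labels."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.clip(np.asarray(scores, dtype=np.float64), eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def compute_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Full report at the given decision threshold (positive iff score > t).

    AUROC/AUPRC need both classes; with a single class present they are
    reported as NaN and flagged.
    """
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    pred = (s > threshold).astype(np.int64)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    flags: List[str] = []
    acc = _ratio(tp + tn, tp + fp + tn + fn, "acc", flags)
    sen = _ratio(tp, tp + fn, "sen", flags)
    spe = _ratio(tn, tn + fp, "spe", flags)
    pre = _ratio(tp, tp + fp, "pre", flags)
    f = _ratio(2 * pre * sen, pre + sen, "f_measure", flags)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", flags)
    if len(np.unique(y)) < 2:
        auroc = float("nan")
        auprc = float("nan")
        flags.append("auroc_undefined")
        flags.append("auprc_undefined")
    else:
        fpr, tpr = roc_curve(y, s)
        auroc = float(_skm.auc(fpr, tpr))
        rec, prec = pr_curve(y, s)
        auprc = float(_skm.auc(rec, prec))
    return MetricsReport(
        loss=bce_loss(y, s),
        acc=acc,
        sen=sen,
        spe=spe,
        pre=pre,
        f_measure=f,
        mcc=mcc,
        auroc=auroc,
        auprc=auprc,
        confusion=(tp, fp, tn, fn),
        flags=flags,
    )


def roc_curve(
    labels: Sequence[int], scores: Sequence[float]
) -> Tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) swept over the unique score thresholds; fpr is monotone."""
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    return fpr, tpr


def pr_curve(
    labels: Sequence[int], scores: Sequence[float]
) -> Tuple[np.ndarray, np.ndarray]:
    """(recall, precision) swept over the unique score thresholds."""
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    return recall, precision
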