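"""Diagnostic evaluation: confusion counts, screening metrics, ROC.

ABNORMAL is the positive class throughout (a false negative is an abnormal
cell or slide called normal — the clinically costly error).  From the counts,

    sensitivity = 100 * TP / (TP + FN)      specificity = 100 * TN / (TN + FP)
    accuracy    = 100 * (TP + TN) / total
    FNR = 100 - sensitivity   FPR = 100 - specificity   error = 100 - accuracy

Raw fractions are kept internally; percentages are rounded (half-up) to two
decimals only at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._errors import ContractError

POSITIVE = "ABNORMAL"
NEGATIVE = "NORMAL"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Screening metrics as percentages (unrounded)."""

    sensitivity: float
    specificity: float
    accuracy: float
    fnr: float
    fpr: float
    classification_error: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Report-style values, rounded half-up."""
        q = Decimal(10) ** -ndigits
        return {
            k: float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))
            for k, v in self.__dict__.items()
        }


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/FP/TN/FN over NORMAL/ABNORMAL label pairs."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ContractError("label sequences differ in length")
    tp = sum(1 for a, b in zip(t, p) if a == POSITIVE and b == POSITIVE)
    fn = sum(1 for a, b in zip(t, p) if a == POSITIVE and b != POSITIVE)
    tn = sum(1 for a, b in zip(t, p) if a != POSITIVE and b != POSITIVE)
    fp = sum(1 for a, b in zip(t, p) if a != POSITIVE and b == POSITIVE)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> Metrics:
    """Screening metrics from confusion counts (percent scale)."""
    if c.tp + c.fn == 0:
        raise ContractError("no positive cases; sensitivity undefined")
    if c.tn + c.fp == 0:
        raise ContractError("no negative cases; specificity undefined")
    sens = 100.0 * c.tp / (c.tp + c.fn)
    spec = 100.0 * c.tn / (c.tn + c.fp)
    acc = 100.0 * (c.tp + c.tn) / c.total
    return Metrics(sensitivity=sens, specificity=spec, accuracy=acc,
                   fnr=100.0 - sens, fpr=100.0 - spec,
                   classification_error=100.0 - acc)


def roc_curve(true_labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over abnormal-posterior scores: (FPR, TPR) points and trapezoid AUC.

    Thresholds sweep the unique scores; the curve is monotone by
    construction.  A single-class truth has no ROC.
    """
    y = np.array([1 if t == POSITIVE else 0 for t in true_labels])
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ContractError("labels and scores differ in length")
    if y.min() == y.max():
        raise ContractError("ROC/AUC undefined for single-class truth")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
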