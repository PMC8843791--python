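"""Confusion-matrix metrics, ROC/AUC, and comparison tables.

The five headline metrics are percentages derived from TP/FP/TN/FN counts:

    accuracy    = (TP + TN) / (TP + TN + FN + FP)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)          (sensitivity, true-positive rate)
    specificity = TN / (TN + FP)          (true-negative rate)
    F1          = 2 P R / (P + R)         (harmonic mean of P and R)

A zero denominator flags the metric as undefined (None) rather than
coercing it to 0.  Rendered percentages are rounded half-up to 2 decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five metrics as percentages in [0, 100]; None when undefined."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None

    def rounded(self) -> dict:
        """Percentages rounded half-up to 2 decimals (display scaling)."""
        out = {}
        for name in ("accuracy", "precision", "recall", "specificity", "f1"):
            v = getattr(self, name)
            out[name] = (None if v is None else
                         float(Decimal(repr(v)).quantize(Decimal("0.01"),
                                                         rounding=ROUND_HALF_UP)))
        return out


@dataclass
class ROCCurve:
    """Threshold-sweep operating points (FPR, TPR) and the trapezoidal AUC."""

    points: np.ndarray  # (k, 2) of (FPR, TPR), FPR non-decreasing
    auc: float


def confusion_matrix(truth, predicted, positive) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with the standard convention: a positive-truth
    sample predicted negative is a false negative; a negative-truth sample
    predicted positive is a false positive."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if not truth:
        raise ValueError("need at least one sample")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The five percentage metrics of a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        precision=precision,
        recall=recall,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        f1=f1,
    )


def roc_curve(scores, truth, positive) -> ROCCurve:
    """ROC by descending-threshold sweep; tied scores share a threshold.

    AUC by the trapezoidal rule, which equals the Mann-Whitney statistic
    (concordant pairs plus half ties over all positive-negative pairs).
    """
    scores = np.asarray(list(scores), dtype=np.float64)
    truth = np.asarray(list(truth), dtype=object)
    if len(scores) != len(truth):
        raise ValueError("scores and truth must have equal length")
    pos = truth == positive
    n_pos = int(pos.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one sample of each class")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    p_sorted = pos[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(s_sorted)):
        tp += int(p_sorted[i])
        fp += int(not p_sorted[i])
        if i + 1 < len(s_sorted) and s_sorted[i + 1] == s_sorted[i]:
            continue  # tied scores share one operating point
        points.append((fp / n_neg, tp / n_pos))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCCurve(points=pts, auc=auc)


def comparison_report(runs) -> pd.DataFrame:
    """Rows of (classifier, TP, FP, TN, FN, five metrics) for a list of
    ``(name, ConfusionMatrix)`` runs, in input order."""
    runs = list(runs)
    if not runs:
        raise ValueError("need at least one run")
    rows = []
    for name, cm in runs:
        m = classification_metrics(cm).rounded()
        rows.append({"classifier": name, "TP": cm.tp, "FP": cm.fp,
                     "TN": cm.tn, "FN": cm.fn, **m})
    return pd.DataFrame(rows)


def report_to_json(name: str, cm: ConfusionMatrix,
                   roc: ROCCurve | None = None) -> str:
    """One run's counts, metrics, and optional ROC as a JSON document."""
    doc = {
        "run_name": name,
        "counts": {"TP": cm.tp, "FP": cm.fp, "TN": cm.tn, "FN": cm.fn},
        "metrics": classification_metrics(cm).rounded(),
    }
    if roc is not None:
        doc["roc"] = {"points": roc.points.tolist(), "auc": roc.auc}
    return json.dumps(doc, indent=2, sort_keys=True)
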