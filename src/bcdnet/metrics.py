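"""Confusion-matrix bookkeeping and classification measures.

All measures derive from the four confusion counts (TP, TN, FP, FN) using
the standard textbook definitions.  Two optimization objectives are built
on top of them:

* phase-1 (feature-gain search) minimizes ``1/accuracy``;
* phase-2 (classifier hyperparameter search) minimizes
  ``1/accuracy + 1/MCC + FNR``, which simultaneously rewards accuracy and
  Matthews correlation while penalizing missed positives — the clinically
  costly error for malignant lesions.

For more than two classes the counts are formed one-vs-rest per class and
macro-averaged; the headline binary report uses a caller-chosen positive
class (malignant by default elsewhere in the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_from_labels",
    "confusion_counts_per_class",
    "multiclass_accuracy",
    "classification_metrics",
    "macro_metrics",
    "phase2_objective_value",
    "roc_points",
]

#: clamp for reciprocals of accuracy / MCC in the objectives
EPSILON = 1e-6


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts: tp, tn, fn, fp (all >= 0)."""

    tp: int
    tn: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}={getattr(self, name)}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fn + self.fp


@dataclass(frozen=True)
class MetricReport:
    """Scalar classification measures computed from one ConfusionCounts.

    ``zero_division_flags`` lists the metrics whose denominator was zero
    (the metric is then reported as 0 by convention).
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    f1: float
    mcc: float
    fnr: float
    fpr: float
    fdr: float
    forate: float
    zero_division_flags: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        d = asdict(self)
        d["zero_division_flags"] = list(self.zero_division_flags)
        return d


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_from_labels(
    true_labels: Sequence,
    pred_labels: Sequence,
    positive_class,
) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``positive_class`` as positive.

    Works for any label alphabet; with more than two classes every label
    other than ``positive_class`` counts as negative.
    """
    true_arr = np.asarray(true_labels)
    pred_arr = np.asarray(pred_labels)
    if true_arr.shape != pred_arr.shape or true_arr.ndim != 1:
        raise ValueError(
            f"label sequences must be 1-D and equal length, got shapes "
            f"{true_arr.shape} and {pred_arr.shape}"
        )
    if true_arr.size == 0:
        raise ValueError("empty label sequences")
    tpos = true_arr == positive_class
    ppos = pred_arr == positive_class
    tp = int(np.sum(tpos & ppos))
    tn = int(np.sum(~tpos & ~ppos))
    fn = int(np.sum(tpos & ~ppos))
    fp = int(np.sum(~tpos & ppos))
    return ConfusionCounts(tp=tp, tn=tn, fn=fn, fp=fp)


def confusion_counts_per_class(
    true_labels: Sequence, pred_labels: Sequence, classes: Sequence | None = None
) -> dict:
    """Per-class one-vs-rest ConfusionCounts for a multi-class problem."""
    true_arr = np.asarray(true_labels)
    if classes is None:
        classes = np.unique(true_arr).tolist()
    return {
        c: confusion_from_labels(true_labels, pred_labels, positive_class=c)
        for c in classes
    }


def multiclass_accuracy(true_labels: Sequence, pred_labels: Sequence) -> float:
    """Fraction of exactly matching labels."""
    true_arr = np.asarray(true_labels)
    pred_arr = np.asarray(pred_labels)
    if true_arr.shape != pred_arr.shape or true_arr.size == 0:
        raise ValueError("label sequences must be non-empty and equal length")
    return float(np.mean(true_arr == pred_arr))


def classification_metrics(counts: ConfusionCounts) -> MetricReport:
    """All scalar measures from one set of confusion counts.

    Any 0/0 ratio is reported as 0 and flagged; an MCC with a zero
    denominator is reported as 0.
    """
    if counts.total <= 0:
        raise ValueError("confusion counts sum to zero")
    tp, tn, fn, fp = counts.tp, counts.tn, counts.fn, counts.fp
    flags: list[str] = []
    accuracy = (tp + tn) / counts.total
    sensitivity = _ratio(tp, tp + fn, "sensitivity", flags)
    specificity = _ratio(tn, tn + fp, "specificity", flags)
    precision = _ratio(tp, tp + fp, "precision", flags)
    npv = _ratio(tn, tn + fn, "npv", flags)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", flags)
    fnr = _ratio(fn, fn + tp, "fnr", flags)
    fpr = _ratio(fp, fp + tn, "fpr", flags)
    fdr = _ratio(fp, fp + tp, "fdr", flags)
    forate = _ratio(fn, fn + tn, "forate", flags)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        npv=npv,
        f1=f1,
        mcc=float(mcc),
        fnr=fnr,
        fpr=fpr,
        fdr=fdr,
        forate=forate,
        zero_division_flags=tuple(flags),
    )


def macro_metrics(
    true_labels: Sequence, pred_labels: Sequence, classes: Sequence | None = None
) -> MetricReport:
    """Macro average of the one-vs-rest MetricReports over all classes."""
    per_class = confusion_counts_per_class(true_labels, pred_labels, classes)
    reports = [classification_metrics(c) for c in per_class.values()]
    fields = [
        "accuracy", "sensitivity", "specificity", "precision", "npv",
        "f1", "mcc", "fnr", "fpr", "fdr", "forate",
    ]
    avg = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    flags = tuple(sorted({f for r in reports for f in r.zero_division_flags}))
    return MetricReport(**avg, zero_division_flags=flags)


def phase2_objective_value(counts: ConfusionCounts) -> float:
    """Hyperparameter-search objective ``1/acc + 1/MCC + FNR`` (minimize).

    Accuracy and MCC are clamped below at ``EPSILON`` so that degenerate
    classifiers (MCC <= 0) receive a very large but finite penalty; the
    minimum value 2.0 is attained exactly by a perfect classifier.
    """
    report = classification_metrics(counts)
    acc = max(report.accuracy, EPSILON)
    mcc = max(report.mcc, EPSILON)
    return 1.0 / acc + 1.0 / mcc + report.fnr


def roc_points(
    scores: Sequence[float], true_labels: Sequence, positive_class=1
) -> tuple[np.ndarray, float]:
    """ROC curve (fpr, tpr) points and trapezoidal area under the curve.

    Thresholds sweep the unique score values from high to low; samples with
    equal scores enter at the same threshold.  Requires at least one
    positive and one negative label.
    """
    scores_arr = np.asarray(scores, dtype=float)
    true_arr = np.asarray(true_labels)
    if scores_arr.shape != true_arr.shape or scores_arr.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(scores_arr)):
        raise ValueError("scores must be finite")
    pos = true_arr == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need at least one positive and one negative")

    order = np.argsort(-scores_arr, kind="stable")
    sorted_scores = scores_arr[order]
    sorted_pos = pos[order].astype(float)
    tp_cum = np.cumsum(sorted_pos)
    fp_cum = np.cumsum(1.0 - sorted_pos)
    # keep only the last index of each tied-score group
    keep = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp_cum[keep] / n_pos]
    fpr = np.r_[0.0, fp_cum[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
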