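"""Cohort splitting, cross-validation and classification metrics.

Splits are stratified by disease class and fully seeded.  AUC is the
rank-based (Mann-Whitney) area under the ROC curve with midrank tie
handling.  The weighted summary metrics average per-class precision,
recall and F1 with weights proportional to true-class support; with that
convention weighted recall is identically the overall accuracy.
Undefined per-class precision (a class never predicted) contributes 0,
with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    class_order: tuple[str, ...]
    counts: np.ndarray  # C x C nonnegative ints

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class MetricsReport:
    class_order: tuple[str, ...]
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display rounding (half-even, like the underlying float round)."""
        return {
            "weighted_precision": round(self.weighted_precision, ndigits),
            "weighted_recall": round(self.weighted_recall, ndigits),
            "weighted_f1": round(self.weighted_f1, ndigits),
            "accuracy": round(self.accuracy, ndigits),
        }


def split_cohort(
    labels: Sequence[str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split; disjoint and exhaustive."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    thin = classes[counts < 2]
    if thin.size:
        raise ValueError(
            f"class(es) {list(thin)} have a single sample; cannot stratify"
        )
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    return np.sort(train), np.sort(test)


def kfold_indices(
    labels: Sequence[str], folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Stratified fold assignment (length-n int array in [0, folds))."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(labels)
    smallest = np.unique(y, return_counts=True)[1].min()
    if folds > smallest:
        logger.warning(
            "requested %d folds but the smallest class has %d samples; "
            "using %d folds", folds, smallest, smallest,
        )
        folds = int(smallest)
        if folds < 2:
            raise ValueError("smallest class too small for any cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=np.int64)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = f
    return assignment


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC with midrank ties; labels are 0/1, score ranks class 1."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined with a single class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def confusion_and_weighted_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_order: Sequence[str],
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix plus per-class and support-weighted P/R/F1."""
    class_order = tuple(class_order)
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    unknown = (set(yt) | set(yp)) - set(class_order)
    if unknown:
        raise ValueError(f"label(s) {sorted(unknown)} not in class_order")
    counts = _sk_confusion(yt, yp, labels=list(class_order))
    cm = ConfusionMatrix(class_order=class_order, counts=counts)
    never = [
        c
        for i, c in enumerate(class_order)
        if counts[:, i].sum() == 0 and counts[i].sum() > 0
    ]
    if never:
        logger.warning(
            "class(es) %s never predicted; their precision counts as 0", never
        )
    return cm, metrics_from_confusion(cm)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Weighted metrics straight from a (possibly externally given) matrix."""
    counts = cm.counts
    support = counts.sum(axis=1).astype(float)
    pred_tot = counts.sum(axis=0).astype(float)
    diag = np.diag(counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, diag / pred_tot, 0.0)
        recall = np.where(support > 0, diag / support, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    total = support.sum()
    w = support / total
    accuracy = diag.sum() / total
    return MetricsReport(
        class_order=cm.class_order,
        precision=precision,
        recall=recall,
        f1=f1,
        weighted_precision=float(w @ precision),
        weighted_recall=float(w @ recall),
        weighted_f1=float(w @ f1),
        accuracy=float(accuracy),
    )


def per_label_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], class_order: Sequence[str]
) -> dict[str, np.ndarray]:
    """Cross-check surface: per-class P/R/F1 via scikit-learn."""
    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=list(class_order), zero_division=0
    )
    return {"precision": p, "recall": r, "f1": f, "support": s}


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Cross-validation summary: mean and sample standard deviation."""
    v = np.asarray(values, dtype=float)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd
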