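"""Evaluation: confusion matrices, per-class metrics, binary aggregation, ROC/AUC.

Conventions: confusion-matrix rows are actual classes and columns predicted
classes; the positive (breakup) group is {area, spot, line}; AUC is the
Mann–Whitney probability that a random breakup frame outscores a random
non-breakup frame, with ties counted half; undefined ratios (0/0) are reported
as NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data import BREAKUP_CLASSES, CLASSES

__all__ = [
    "ConfusionMatrix",
    "ROCResult",
    "confusion",
    "per_class_metrics",
    "f1_from_precision_recall",
    "aggregate_binary",
    "roc_auc",
    "auc_ci95",
    "operating_point",
    "crossval_summary",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints, rows = actual, cols = predicted
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be KxK for K classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.class_order != self.class_order:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.class_order)


@dataclass
class ROCResult:
    points: np.ndarray  # (n, 2) of (FPR, TPR), sorted along the sweep
    thresholds: np.ndarray
    auc: float
    ci95: tuple[float, float] | None = None
    operating: tuple[float, float] | None = None  # (sensitivity, specificity)


def confusion(actual, predicted, class_order=CLASSES) -> ConfusionMatrix:
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    known = set(class_order)
    for lab in actual + predicted:
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
    k = len(class_order)
    if not actual:
        return ConfusionMatrix(np.zeros((k, k), dtype=int), tuple(class_order))
    counts = _sk_confusion(actual, predicted, labels=list(class_order))
    return ConfusionMatrix(counts, tuple(class_order))


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Recall, precision and F1 per class plus overall accuracy.

    Returns a DataFrame indexed by class with columns recall/precision/f1;
    overall accuracy is stored in ``df.attrs["accuracy"]``. Zero denominators
    yield NaN.
    """
    diag = np.diag(cm.counts).astype(float)
    row = cm.counts.sum(axis=1).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, diag / row, np.nan)
        precision = np.where(col > 0, diag / col, np.nan)
    f1 = f1_from_precision_recall(precision, recall)
    df = pd.DataFrame(
        {"recall": recall, "precision": precision, "f1": f1},
        index=list(cm.class_order),
    )
    df.attrs["accuracy"] = float(diag.sum() / cm.total) if cm.total else np.nan
    return df


def f1_from_precision_recall(precision, recall):
    """Harmonic mean 2PR/(P+R); NaN where either input is NaN or both are zero."""
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, np.nan)
    f1 = np.where(np.isnan(precision) | np.isnan(recall), np.nan, f1)
    return float(f1) if f1.ndim == 0 else f1


@dataclass
class BinarySummary:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def aggregate_binary(cm9: ConfusionMatrix) -> BinarySummary:
    """Collapse the nine-class matrix to breakup (positive) vs non-breakup."""
    pos = np.array([c in BREAKUP_CLASSES for c in cm9.class_order])
    c = cm9.counts
    tp = int(c[np.ix_(pos, pos)].sum())
    fn = int(c[np.ix_(pos, ~pos)].sum())
    fp = int(c[np.ix_(~pos, pos)].sum())
    tn = int(c[np.ix_(~pos, ~pos)].sum())
    return BinarySummary(tp=tp, fp=fp, fn=fn, tn=tn)


def _validate_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative label")
    return scores, labels


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC over frame scores.

    AUC is the midrank Mann–Whitney statistic
    P(score+ > score−) + ½·P(score+ = score−); curve points come from sweeping
    every distinct score as an inclusive threshold.
    """
    scores, labels = _validate_scores(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # midranks
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores, drop_intermediate=False)
    return ROCResult(points=np.column_stack([fpr, tpr]), thresholds=thr, auc=float(auc))


def _delong_variance(scores, labels):
    """DeLong placement-based variance of the empirical AUC."""
    x = scores[labels]  # positives
    y = scores[~labels]
    m, n = x.size, y.size
    all_r = rankdata(np.concatenate([x, y]))
    rx = rankdata(x)
    ry = rankdata(y)
    # placements: V10_i = fraction of negatives a positive beats (ties half)
    v10 = (all_r[:m] - rx) / n
    v01 = 1.0 - (all_r[m:] - ry) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci95(
    scores,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% confidence interval for the AUC, clipped to [0, 1].

    ``delong`` (default): placement-based variance with a normal interval.
    ``bootstrap``: stratified percentile bootstrap with ``n_boot`` resamples.
    """
    scores, labels = _validate_scores(scores, labels)
    if method == "delong":
        auc, var = _delong_variance(scores, labels)
        half = 1.959963984540054 * float(np.sqrt(var))
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = scores[labels]
        neg = scores[~labels]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            ps = rng.choice(pos, pos.size, replace=True)
            ns = rng.choice(neg, neg.size, replace=True)
            r = rankdata(np.concatenate([ps, ns]))
            aucs[b] = (r[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
                pos.size * neg.size
            )
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        return (max(0.0, float(lo)), min(1.0, float(hi)))
    raise ValueError(f"unknown CI method {method!r}")


def operating_point(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the inclusive rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    decision = scores >= threshold
    pos = labels.sum()
    neg = labels.size - pos
    sens = float((decision & labels).sum() / pos) if pos else float("nan")
    spec = float((~decision & ~labels).sum() / neg) if neg else float("nan")
    return sens, spec


def crossval_summary(per_fold: dict[str, list[float]] | pd.DataFrame) -> pd.DataFrame:
    """Mean and sample (n−1) standard deviation of each metric across folds."""
    df = pd.DataFrame(per_fold)
    if len(df) < 2:
        raise ValueError("need at least 2 folds to summarize")
    return pd.DataFrame({"mean": df.mean(axis=0), "sd": df.std(axis=0, ddof=1)})
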