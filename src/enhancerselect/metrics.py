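"""Classifier metrics and score correlations.

auROC is the probability that a random positive outscores a random negative
(ties counting one half); a random classifier sits at 0.5.  auPRC uses the
average-precision (step) convention, whose random baseline equals the
positive fraction; trapezoidal interpolation is deliberately avoided as
optimistic.  F1 is evaluated at a fixed decision threshold (0 for SVM
decision scores, 0.5 for CNN probabilities), with the convention F1 = 0
when nothing is predicted positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

__all__ = [
    "MetricReport",
    "auroc",
    "auprc",
    "f1_at_threshold",
    "correlate_scores",
    "evaluate",
]


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank-statistic / pairwise-concordance form)."""
    labels = _check_two_classes(labels)
    return float(_skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve, average-precision convention."""
    labels = _check_two_classes(labels)
    return float(_skm.average_precision_score(
        labels, np.asarray(scores, dtype=float)))


def f1_at_threshold(scores, labels, threshold: float) -> float:
    """F1 with predicted-positive <=> score > threshold; 0 if none predicted."""
    labels = np.asarray(labels, dtype=int)
    predicted = (np.asarray(scores, dtype=float) > threshold).astype(int)
    return float(_skm.f1_score(labels, predicted, zero_division=0))


def correlate_scores(x, y) -> tuple[float, float]:
    """(Pearson, Spearman) correlations; Spearman uses mean ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


@dataclass
class MetricReport:
    auroc: float
    auprc: float
    f1: float
    n_pos: int
    n_neg: int
    roc_curve: tuple[np.ndarray, np.ndarray]   # (fpr, tpr)
    pr_curve: tuple[np.ndarray, np.ndarray]    # (recall, precision)


def evaluate(scores, labels, threshold: float = 0.0) -> MetricReport:
    """Full metric report for one score vector."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    return MetricReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        f1=f1_at_threshold(scores, labels, threshold),
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
        roc_curve=(fpr, tpr),
        pr_curve=(recall, precision))
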