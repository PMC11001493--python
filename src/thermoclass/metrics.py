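"""Binary-classification metric panel and embedding QC.

The panel is computed from first principles: MCC and friends from the 2x2
confusion matrix, ROC AUC as the rank (Mann-Whitney) statistic — exact under
ties — and PR AUC by step-wise summation over descending score cut-points
(average-precision style, not trapezoidal).  PCA for embedding QC is a thin
wrapper over scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "mcc",
    "accuracy",
    "precision",
    "recall",
    "specificity",
    "f1",
    "roc_auc",
    "pr_auc",
    "metrics_report",
    "pca2",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    mcc: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    roc_auc: float
    pr_auc: float


def _check_binary(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isin(arr, (0, 1))):
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(int)


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionMatrix:
    """Count the 2x2 confusion matrix; TP means label 1 and call 1."""
    y = _check_binary(labels, "labels")
    c = _check_binary(calls, "calls")
    if len(y) != len(c):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(c)} calls")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (c == 1))),
        fp=int(np.sum((y == 0) & (c == 1))),
        tn=int(np.sum((y == 0) & (c == 0))),
        fn=int(np.sum((y == 1) & (c == 0))),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any margin of the matrix is 0."""
    tp, fp, tn, fn = (float(x) for x in (cm.tp, cm.fp, cm.tn, cm.fn))
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom_sq)


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    return cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else 0.0


def recall(cm: ConfusionMatrix) -> float:
    return cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0


def specificity(cm: ConfusionMatrix) -> float:
    return cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else 0.0


def f1(cm: ConfusionMatrix) -> float:
    p, r = precision(cm), recall(cm)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability that a random positive outranks a random negative.

    Rank-statistic formulation (ties count one half), equivalent to the
    area under the ROC curve with linear tie interpolation.
    """
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores length mismatch")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve by step summation.

    Sum of (R_i - R_{i-1}) * P_i over descending unique score cut-points —
    the average-precision estimator, with tied scores grouped into one step.
    """
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores length mismatch")
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise ValueError("pr_auc requires at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = 0
    fp = 0
    area = 0.0
    prev_recall = 0.0
    i = 0
    n = len(y_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j] == 1)
            fp += int(y_sorted[j] == 0)
            j += 1
        recall_i = tp / n_pos
        precision_i = tp / (tp + fp)
        area += (recall_i - prev_recall) * precision_i
        prev_recall = recall_i
        i = j
    return area


def metrics_report(
    labels: Sequence[int], calls: Sequence[int], scores: Sequence[float]
) -> MetricsReport:
    """Full metric panel from hard calls plus ranking scores."""
    cm = confusion(labels, calls)
    return MetricsReport(
        mcc=mcc(cm),
        accuracy=accuracy(cm),
        precision=precision(cm),
        recall=recall(cm),
        specificity=specificity(cm),
        f1=f1(cm),
        roc_auc=roc_auc(labels, scores),
        pr_auc=pr_auc(labels, scores),
    )


def pca2(vectors: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Two-component PCA of a set of embedding vectors.

    Returns (n x 2 coordinates, explained-variance fractions of the first
    two components, descending).  Used as the quick visual QC that class
    signal is present in mean embeddings.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("pca2 needs at least 3 vectors of dimension >= 2")
    if np.allclose(X, X[0]):
        raise ValueError("pca2 on rank-0 data (all vectors identical)")
    model = PCA(n_components=2, svd_solver="full")
    coords = model.fit_transform(X)
    return coords, model.explained_variance_ratio_.copy()
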