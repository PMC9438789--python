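"""Prediction-accuracy metrics for polygenic scores.

R^2 (squared Pearson correlation) for quantitative traits, rank-based
(Mann-Whitney) AUC and ROC curves for binary traits, and case-prevalence
summaries in the tails of the score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.stats import rankdata


@dataclass
class EvaluationReport:
    r2: float | None
    auc: float | None
    roc_points: list | None
    prevalence_table: dict | None  # (q, 'top'|'bottom') -> case fraction
    fold_changes: dict | None  # q -> top/bottom ratio (None if undefined)


def r2_metric(prs: np.ndarray, phenotype: np.ndarray) -> float:
    """Squared Pearson correlation between score and phenotype."""
    prs = np.asarray(prs, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if prs.shape != y.shape or prs.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(prs) == 0 or np.std(y) == 0:
        raise ValueError("R^2 is undefined for a constant vector")
    return float(np.corrcoef(prs, y)[0, 1] ** 2)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2 or not set(classes).issubset({0, 1}):
        raise ValueError("labels must contain both classes, coded 0/1")
    return labels.astype(int)


def auc_metric(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(case score > control score), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """ROC points (FPR, TPR) at every distinct threshold, descending.

    Tied scores are grouped into a single step so the trapezoidal area
    under the returned polyline equals the Mann-Whitney AUC exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    n1 = int(labels.sum())
    n0 = labels.size - n1
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(l)[distinct]
    fps = distinct + 1 - tps
    points = [(0.0, 0.0)] + [
        (fp / n0, tp / n1) for fp, tp in zip(fps.tolist(), tps.tolist())
    ]
    return points


def roc_auc(roc_points) -> float:
    """Trapezoidal area under an ROC polyline."""
    pts = np.asarray(roc_points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def prevalence_quantiles(
    scores: np.ndarray, labels: np.ndarray, quantiles=(0.02, 0.05, 0.10)
):
    """Case prevalence in the extreme tails of the score distribution.

    For each quantile q the bottom bin holds the ceil(q*n) lowest-scoring
    samples and the top bin the ceil(q*n) highest (stable sort breaks
    ties); prevalence is the case fraction within the bin and fold_change
    the top/bottom ratio (None when the bottom bin has no cases).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not set(np.unique(labels)).issubset({0, 1}):
        raise ValueError("labels must be coded 0/1")
    labels = labels.astype(int)  # a single class is fine for prevalences
    n = scores.size
    order = np.argsort(scores, kind="stable")
    table: dict = {}
    fold: dict = {}
    for q in quantiles:
        k = ceil(q * n)
        if k == 0 or k > n:
            raise ValueError(f"quantile {q} yields an empty bin at n={n}")
        bottom = labels[order[:k]].mean()
        top = labels[order[-k:]].mean()
        table[(q, "bottom")] = float(bottom)
        table[(q, "top")] = float(top)
        fold[q] = float(top / bottom) if bottom > 0 else None
    return table, fold


def evaluate(
    scores: np.ndarray,
    phenotype: np.ndarray,
    binary: bool | None = None,
    quantiles=(0.02, 0.05, 0.10),
) -> EvaluationReport:
    """One-stop report: auto-selects R^2 vs AUC by phenotype type.

    ``binary=None`` detects a 0/1-coded phenotype; quantitative traits get
    only R^2, binary traits get AUC, the ROC curve and tail prevalences.
    """
    y = np.asarray(phenotype, dtype=float)
    if binary is None:
        binary = set(np.unique(y)).issubset({0.0, 1.0})
    if binary:
        pts = roc_curve(scores, y)
        table, fold = prevalence_quantiles(scores, y, quantiles)
        return EvaluationReport(
            r2=None,
            auc=auc_metric(scores, y),
            roc_points=pts,
            prevalence_table=table,
            fold_changes=fold,
        )
    return EvaluationReport(
        r2=r2_metric(scores, y),
        auc=None,
        roc_points=None,
        prevalence_table=None,
        fold_changes=None,
    )
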