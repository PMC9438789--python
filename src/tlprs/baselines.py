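"""Comparator multi-population PRS methods.

Two baselines against which the transfer fit is compared:

* fixed-effect inverse-variance meta-analysis of two populations'
  summary statistics, followed by any single-population PRS method;
* PT-Multi: per-population LD clumping + p-value thresholding, with the
  per-population scores linearly combined using regression weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .genio import GenotypePanel, SummaryStats, harmonize_variants
from .lassosum import score_prs

logger = logging.getLogger(__name__)

# p-value thresholding grid used throughout (densest at the significant end)
DEFAULT_P_GRID = (1.0, 0.3, 0.1, 3e-2, 1e-2, 3e-3, 1e-3, 3e-4, 1e-4)
DEFAULT_R2_THRESHOLD = 0.1
DEFAULT_CLUMP_WINDOW = 250_000


@dataclass
class ClumpResult:
    """Outcome of greedy LD clumping.

    ``index_variants`` are the retained variant indices in retention
    order; ``assignments`` maps each removed variant to the retained
    variant that displaced it.
    """

    index_variants: list
    assignments: dict


@dataclass
class PTMultiFit:
    """Combined clumping+thresholding fit over several populations."""

    thresholds: list  # per-population selected p threshold
    prs_per_population: list  # per-population PRS vectors
    intercept: float
    weights: np.ndarray
    combined_prs: np.ndarray
    cv_score: float | None = None


def meta_combine(stats_a: SummaryStats, stats_e: SummaryStats) -> SummaryStats:
    """Fixed-effect inverse-variance meta-analysis of two populations.

    On the harmonized variant intersection:
        beta_ma = (beta_a/se_a^2 + beta_e/se_e^2) / (1/se_a^2 + 1/se_e^2)
        se_ma   = 1 / sqrt(1/se_a^2 + 1/se_e^2)
        z_ma    = beta_ma / se_ma,  p = 2 Phi(-|z_ma|).
    """
    same = len(stats_a.variants) == len(stats_e.variants) and stats_a.variants[
        ["id", "a1", "a2"]
    ].equals(stats_e.variants[["id", "a1", "a2"]])
    if same:  # already aligned: skip the harmonization pass
        a, e = stats_a, stats_e
    else:
        (a, e), _ = harmonize_variants([stats_a, stats_e], [])
    if a.n_variants == 0:
        raise ValueError("no shared variants to meta-analyze")
    w_a = 1.0 / a.se**2
    w_e = 1.0 / e.se**2
    beta_ma = (a.beta * w_a + e.beta * w_e) / (w_a + w_e)
    se_ma = 1.0 / np.sqrt(w_a + w_e)
    z = beta_ma / se_ma
    pval = np.clip(2.0 * sps.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return SummaryStats(
        variants=a.variants,
        beta=beta_ma,
        se=se_ma,
        pval=pval,
        n=a.n + e.n,
        tstat=z,
    )


def clump(
    stats: SummaryStats,
    panel: GenotypePanel,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window: int = DEFAULT_CLUMP_WINDOW,
) -> ClumpResult:
    """Greedy p-value-ordered LD clumping against a reference panel.

    Variants are visited by ascending p (ties by position, then id); a
    variant is retained unless its reference-panel r^2 with an
    already-retained variant within ``window`` bp on the same chromosome
    exceeds ``r2_threshold``, in which case it is assigned to the first
    such retained variant.
    """
    if list(panel.variants["id"]) != list(stats.variants["id"]):
        raise ValueError("panel must be aligned to the summary statistics")
    Z = panel.standardized()
    n = panel.n_samples
    chrom = stats.variants["chrom"].to_numpy()
    pos = stats.variants["pos"].to_numpy()
    ids = stats.variants["id"].to_numpy()
    order = np.lexsort((ids, pos, stats.pval))

    retained: list[int] = []
    assignments: dict[int, int] = {}
    for j in order:
        blocker = None
        for k in retained:
            if chrom[k] != chrom[j] or abs(int(pos[k]) - int(pos[j])) > window:
                continue
            r = float(Z[:, j] @ Z[:, k]) / n
            if r * r > r2_threshold:
                blocker = k
                break
        if blocker is None:
            retained.append(int(j))
        else:
            assignments[int(j)] = blocker
    return ClumpResult(index_variants=retained, assignments=assignments)


def _is_binary(y: np.ndarray) -> bool:
    return set(np.unique(y)).issubset({0.0, 1.0})


def _cv_score(prs: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """Mean out-of-fold R^2 (quantitative) or logistic AUC (binary)."""
    from .evaluate import auc_metric, r2_metric

    binary = _is_binary(y)
    if binary:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(prs.reshape(-1, 1), y)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(prs.reshape(-1, 1))
    scores = []
    for train, test in split:
        if binary:
            model = LogisticRegression(max_iter=1000)
            model.fit(prs[train].reshape(-1, 1), y[train])
            pred = model.decision_function(prs[test].reshape(-1, 1))
            if len(np.unique(y[test])) < 2:
                continue
            scores.append(auc_metric(pred, y[test]))
        else:
            if test.size < 3 or np.std(prs[test]) == 0 or np.std(y[test]) == 0:
                scores.append(0.0)
            else:
                scores.append(r2_metric(prs[test], y[test]))
    return float(np.mean(scores)) if scores else -np.inf


def pt_single_best(
    stats: SummaryStats,
    clump_result: ClumpResult,
    panel_val: GenotypePanel,
    p_grid=DEFAULT_P_GRID,
    folds: int = 10,
    seed: int = 0,
):
    """Select the best p-value threshold for one population by 10-fold CV.

    For each threshold the PRS is built from the clumped variants with
    p <= threshold using their marginal effect sizes; the threshold with
    the highest mean cross-validated R^2 (or AUC for a binary phenotype)
    on the validation panel wins. Thresholds retaining no variant are
    skipped. Returns ``(best_threshold, prs_vector)``.
    """
    if panel_val.phenotype is None:
        raise ValueError("validation panel must carry a phenotype")
    y = panel_val.phenotype
    retained = np.array(clump_result.index_variants, dtype=np.int64)
    best_t, best_score, best_prs = None, -np.inf, None
    for thr in p_grid:
        sel = retained[stats.pval[retained] <= thr]
        if sel.size == 0:
            logger.info("threshold %g retains no variants; skipped", thr)
            continue
        beta = np.zeros(stats.n_variants)
        beta[sel] = stats.beta[sel]
        prs = score_prs(panel_val, beta)
        score = _cv_score(prs, y, folds, seed)
        if score > best_score:
            best_t, best_score, best_prs = thr, score, prs
    if best_t is None:
        raise ValueError("every p-value threshold retained zero variants")
    return best_t, best_prs


def pt_multi_combine(
    prs_per_population,
    phenotype: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> PTMultiFit:
    """Linearly combine per-population PRS with regression weights.

    Weights come from least squares (quantitative phenotype) or logistic
    regression (binary), always with an intercept; the combined PRS is
    the fitted linear predictor. Constant PRS columns get weight 0 with a
    warning. A seeded ``folds``-fold CV score of the combined score is
    attached for reporting.
    """
    prs_list = [np.asarray(p, dtype=float) for p in prs_per_population]
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if any(p.shape != (n,) for p in prs_list):
        raise ValueError("all PRS vectors must match the phenotype length")

    keep = []
    for i, p in enumerate(prs_list):
        if np.std(p) == 0:
            warnings.warn(
                f"PRS column {i} is constant; its weight is set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            keep.append(i)
    X = np.column_stack([prs_list[i] for i in keep]) if keep else np.empty((n, 0))

    weights = np.zeros(len(prs_list))
    if _is_binary(y) and keep:
        model = LogisticRegression(max_iter=1000)
        model.fit(X, y)
        intercept = float(model.intercept_[0])
        weights[keep] = model.coef_[0]
    elif keep:
        design = np.column_stack([np.ones(n), X])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept = float(coef[0])
        weights[keep] = coef[1:]
    else:
        intercept = float(np.mean(y))

    combined = intercept + np.column_stack(prs_list) @ weights
    cv = _cv_score(combined, y, folds, seed) if keep else None
    return PTMultiFit(
        thresholds=[],
        prs_per_population=prs_list,
        intercept=intercept,
        weights=weights,
        combined_prs=combined,
        cv_score=cv,
    )


def pt_multi(
    stats_list,
    panel_val: GenotypePanel,
    p_grid=DEFAULT_P_GRID,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window: int = DEFAULT_CLUMP_WINDOW,
    folds: int = 10,
    seed: int = 0,
) -> PTMultiFit:
    """Full PT-Multi: clump + threshold each population, then combine.

    Every population's summary statistics must already be aligned to the
    validation panel's variants. The panel doubles as LD reference for
    clumping and as the individual-level data for CV threshold selection
    and mixing weights.
    """
    thresholds, prs_list = [], []
    for stats in stats_list:
        cl = clump(stats, panel_val, r2_threshold=r2_threshold, window=window)
        thr, prs = pt_single_best(
            stats, cl, panel_val, p_grid=p_grid, folds=folds, seed=seed
        )
        thresholds.append(thr)
        prs_list.append(prs)
    fit = pt_multi_combine(prs_list, panel_val.phenotype, folds=folds, seed=seed)
    fit.thresholds = thresholds
    return fit
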