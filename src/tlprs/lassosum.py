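"""Summary-statistics lasso (Lassosum) solved blockwise by coordinate descent.

The objective, maximized per LD block b over coefficients beta, is

    2 r_b' beta - beta' R_s,b beta - 2 lambda ||beta||_1,

where r are SNP-wise correlations derived from GWAS t-statistics,
R_s = (1 - s) R + s I is the shrunk LD matrix from a reference panel
(shrinkage s in (0, 1] guarantees positive-definiteness), and lambda is
the L1 penalty. Tuning parameters (s, lambda) are selected without
phenotype data by pseudovalidation: the projected-correlation score
r' beta / sqrt(beta' R_s beta).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genio import GenotypePanel, LDBlocks, SummaryStats

logger = logging.getLogger(__name__)

DEFAULT_S_GRID = (0.2, 0.5, 0.9, 1.0)
DEFAULT_LAMBDA_GRID = tuple(np.geomspace(0.1, 0.001, 20))


class AllZeroPathError(ValueError):
    """Every candidate coefficient vector is identically zero."""


@dataclass
class LassosumConfig:
    """Tuning grids and solver controls for the blockwise lasso."""

    s_grid: tuple = DEFAULT_S_GRID
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    max_iter: int = 1000
    tol: float = 1e-4

    def __post_init__(self) -> None:
        self.s_grid = tuple(float(s) for s in self.s_grid)
        self.lambda_grid = tuple(float(l) for l in self.lambda_grid)
        if not self.s_grid or not self.lambda_grid:
            raise ValueError("tuning grids must be non-empty")
        if any(not (0 < s <= 1) for s in self.s_grid):
            raise ValueError("shrinkage values must lie in (0, 1]")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("penalties must be positive")
        diffs = np.diff(self.lambda_grid)
        if np.any(diffs >= 0):
            raise ValueError("lambda_grid must be strictly decreasing")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class BlockLD:
    """Per-block LD correlation matrices plus the variant index lists."""

    matrices: list  # block index -> (p_b x p_b) correlation matrix
    variant_indices: list  # block index -> int array of variant columns
    n_variants: int

    def __post_init__(self) -> None:
        covered = np.concatenate([np.asarray(ix) for ix in self.variant_indices])
        if len(np.unique(covered)) != len(covered):
            raise ValueError("a variant is assigned to more than one block")

    def quadratic_form(self, beta: np.ndarray, s: float) -> float:
        """beta' R_s beta with R_s = (1-s) R + s I (blocks independent)."""
        total = s * float(beta @ beta)
        if s < 1.0:
            for R, ix in zip(self.matrices, self.variant_indices):
                b = beta[ix]
                total += (1.0 - s) * float(b @ R @ b)
        return total


@dataclass
class EffectPath:
    """Lasso coefficient vectors over the (s, lambda) grid.

    ``coefficients[(s, lam)]`` is the full-length coefficient vector;
    ``pseudoval_score`` holds the selection score per grid point, and
    ``selected``/``beta_opt`` the pseudovalidation optimum.
    """

    coefficients: dict
    pseudoval_score: dict = field(default_factory=dict)
    validation_score: dict = field(default_factory=dict)
    selected: tuple | None = None

    @property
    def beta_opt(self) -> np.ndarray:
        if self.selected is None:
            raise ValueError("path has not been pseudovalidated")
        return self.coefficients[self.selected]


def tstat_to_correlation(tstat, n) -> np.ndarray:
    """SNP-wise correlation from the GWAS t-statistic: r = t / sqrt(n-1+t^2)."""
    tstat = np.asarray(tstat, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("per-variant sample size must be at least 2")
    return tstat / np.sqrt(n - 1.0 + tstat**2)


def ensure_r(stats: SummaryStats, clip: float = 0.999) -> np.ndarray:
    """Fill (and return) stats.r from the t-statistics if absent."""
    if stats.r is None:
        stats.r = np.clip(tstat_to_correlation(stats.tstat, stats.n), -clip, clip)
    return stats.r


def compute_block_ld(panel: GenotypePanel, blocks: LDBlocks) -> BlockLD:
    """Blockwise LD correlation matrices R = Z'Z / n from a reference panel.

    Z is the standardized (mean-imputed) dosage matrix, so each matrix has
    unit diagonal; constant variants get zero correlations. Blocks with no
    variants are skipped.
    """
    assignment = blocks.assign(panel.variants)
    Z = panel.standardized()
    n = panel.n_samples
    matrices, indices = [], []
    for b in range(blocks.n_blocks):
        ix = np.flatnonzero(assignment == b)
        if ix.size == 0:
            continue
        Zb = Z[:, ix]
        R = (Zb.T @ Zb) / n
        const = Zb.std(axis=0) == 0
        R[const, :] = 0.0
        R[:, const] = 0.0
        np.fill_diagonal(R, 1.0)
        np.clip(R, -1.0, 1.0, out=R)
        R = (R + R.T) / 2.0
        matrices.append(R)
        indices.append(ix)
    unassigned = int((assignment == -1).sum())
    if unassigned:
        logger.warning("%d variants fall outside every LD block", unassigned)
    return BlockLD(matrices=matrices, variant_indices=indices, n_variants=panel.n_variants)


def soft_threshold(x: float, lam: float):
    """Soft-thresholding operator sign(x) * max(|x| - lam, 0)."""
    if np.any(np.asarray(lam) < 0):
        raise ValueError("threshold must be non-negative")
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


# --- coordinate-descent kernel (numba-accelerated when available) ----------


def _cd_sweeps(Rs, r, beta, lam, max_iter, tol):
    p = r.shape[0]
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            old = beta[j]
            # partial residual correlation excluding j's own contribution
            z = r[j] - (Rs[j] @ beta) + Rs[j, j] * old
            az = abs(z)
            new = 0.0 if az <= lam else np.sign(z) * (az - lam) / Rs[j, j]
            if new != old:
                beta[j] = new
                d = abs(new - old)
                if d > max_delta:
                    max_delta = d
        if max_delta < tol:
            return beta, True
    return beta, False


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _cd_sweeps = njit(cache=False)(_cd_sweeps)
except ImportError:  # pragma: no cover
    pass


def block_coordinate_descent(
    r_block: np.ndarray,
    R_block: np.ndarray,
    s: float,
    lam: float,
    init: np.ndarray | None = None,
    config: LassosumConfig | None = None,
    block_id=None,
) -> np.ndarray:
    """Solve one block of the shrunk-LD lasso by cyclic coordinate descent.

    Updates beta_j <- soft(r_j - sum_{k != j} (R_s)_{jk} beta_k, lam) / (R_s)_{jj}
    until the largest coefficient change in a sweep falls below ``tol``.
    Non-convergence returns the last iterate with a warning.
    """
    config = config or LassosumConfig()
    r_block = np.asarray(r_block, dtype=float)
    R_block = np.asarray(R_block, dtype=float)
    if not (0 <= s <= 1):
        # s = 0 (no shrinkage, raw R) is permitted here for well-conditioned
        # blocks; the grid-level config still requires s > 0.
        raise ValueError("shrinkage s must be in [0, 1]")
    if R_block.shape != (r_block.size, r_block.size):
        raise ValueError("R_block dimensions do not match r_block")
    Rs = (1.0 - s) * R_block + s * np.eye(r_block.size)
    beta = np.zeros_like(r_block) if init is None else np.array(init, dtype=float)
    beta, converged = _cd_sweeps(
        Rs, r_block, beta, float(lam), int(config.max_iter), float(config.tol)
    )
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {config.max_iter} sweeps"
            + (f" (block {block_id})" if block_id is not None else ""),
            RuntimeWarning,
            stacklevel=2,
        )
    return beta


def lasso_objective(beta, r, blockld: BlockLD, s, lam) -> float:
    """2 r' beta - beta' R_s beta - 2 lam ||beta||_1 (the maximized objective)."""
    return (
        2.0 * float(r @ beta)
        - blockld.quadratic_form(beta, s)
        - 2.0 * lam * float(np.abs(beta).sum())
    )


def fit_lassosum_path(
    stats: SummaryStats,
    blockld: BlockLD,
    config: LassosumConfig | None = None,
    r: np.ndarray | None = None,
    pseudovalidation: bool = True,
    allow_all_zero: bool = False,
) -> EffectPath:
    """Fit the lasso over the full (s, lambda) grid, block by block.

    Blocks are solved independently with warm starts along the descending
    lambda grid. When ``pseudovalidation`` is set the path is scored and
    the optimum selected. ``r`` overrides the correlation vector (used by
    the transfer offset step); otherwise it is derived from ``stats``.
    """
    config = config or LassosumConfig()
    if r is None:
        r = ensure_r(stats)
    r = np.asarray(r, dtype=float)
    p = blockld.n_variants
    if r.size != p:
        raise ValueError("correlation vector length does not match the LD panel")

    coefficients = {
        (s, lam): np.zeros(p) for s in config.s_grid for lam in config.lambda_grid
    }
    for s in config.s_grid:
        for R, ix in zip(blockld.matrices, blockld.variant_indices):
            beta_b = np.zeros(ix.size)
            for lam in config.lambda_grid:  # descending: warm starts
                beta_b = block_coordinate_descent(
                    r[ix], R, s, lam, init=beta_b, config=config
                )
                coefficients[(s, lam)][ix] = beta_b
    path = EffectPath(coefficients=coefficients)
    if pseudovalidation:
        pseudovalidate(path, stats, blockld, r=r, allow_all_zero=allow_all_zero)
    return path


def pseudovalidate(
    path: EffectPath,
    stats: SummaryStats | None,
    blockld: BlockLD,
    r: np.ndarray | None = None,
    allow_all_zero: bool = False,
) -> EffectPath:
    """Score every grid point and select the optimum without phenotypes.

    The score is the projected correlation r' beta / sqrt(beta' R_s beta)
    (scale-invariant; -inf for the all-zero vector). Ties are broken
    toward larger lambda, i.e. the sparser model. When every candidate is
    all-zero the default is to raise; ``allow_all_zero`` instead selects
    the largest-penalty grid point with a zero vector (meaningful for the
    transfer offset, where an all-zero solution is a valid outcome).
    """
    if r is None:
        if stats is None:
            raise ValueError("either stats or r must be provided")
        r = ensure_r(stats)
    best, best_score = None, -np.inf
    for (s, lam), beta in path.coefficients.items():
        if np.any(beta):
            denom = blockld.quadratic_form(beta, s)
            score = float(r @ beta) / np.sqrt(denom) if denom > 0 else -np.inf
        else:
            score = -np.inf
        path.pseudoval_score[(s, lam)] = score
        if score > best_score:  # strict: ties keep the earlier, larger lambda
            best, best_score = (s, lam), score
    if best is None:
        if not allow_all_zero:
            raise AllZeroPathError(
                "every candidate on the path is identically zero; "
                "extend lambda_grid toward smaller penalties"
            )
        best = max(path.coefficients, key=lambda k: k[1])
    path.selected = best
    return path


def select_by_validation(
    path: EffectPath,
    panel: GenotypePanel,
    phenotype: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    offset_beta: np.ndarray | None = None,
) -> EffectPath:
    """Select (s, lambda) by cross-validated R^2 on individual-level data.

    For every grid point the PRS is computed on the validation panel and
    scored by the mean squared Pearson correlation with the phenotype
    across ``folds`` seeded folds; the grid point with the highest mean
    wins (ties toward larger lambda). ``offset_beta`` is added to each
    candidate before scoring, so the selection can optimize a combined
    predictor (used by the transfer offset step). This is the tuning mode
    for when a phenotyped validation panel exists; pseudovalidation is
    the summary-data-only alternative.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (panel.n_samples,):
        raise ValueError("phenotype length must match the validation panel")
    Z = panel.standardized()
    rng = np.random.default_rng(seed)
    fold_ids = rng.permutation(panel.n_samples) % folds
    best, best_score = None, -np.inf
    for key, beta in path.coefficients.items():
        full = beta if offset_beta is None else beta + offset_beta
        prs = Z @ full
        scores = []
        for f in range(folds):
            mask = fold_ids == f
            pf, yf = prs[mask], y[mask]
            if pf.size < 3 or np.std(pf) == 0 or np.std(yf) == 0:
                scores.append(0.0)
            else:
                scores.append(float(np.corrcoef(pf, yf)[0, 1] ** 2))
        score = float(np.mean(scores))
        path.validation_score[key] = score
        if score > best_score:
            best, best_score = key, score
    path.selected = best
    return path


def score_prs(
    panel: GenotypePanel, beta: np.ndarray, variants=None
) -> np.ndarray:
    """Polygenic score per sample: standardized dosages times beta.

    ``variants`` (optional) must list the variant ids beta refers to, in
    order; a mismatch with the panel is an error rather than a silent
    reorder. Missing dosages contribute 0 (the post-standardization mean).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size != panel.n_variants:
        raise ValueError(
            f"beta has {beta.size} entries but panel has {panel.n_variants} variants"
        )
    if variants is not None:
        ids = list(variants["id"]) if hasattr(variants, "columns") else list(variants)
        if list(panel.variants["id"]) != ids:
            raise ValueError("variant order mismatch between panel and beta")
    return panel.standardized() @ beta
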