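"""Transfer-learning PRS across ancestries (TL-Multi).

A large auxiliary-population GWAS (typically European) is fit first with
the summary-statistics lasso, giving effects beta_e. The target
population's effects are modeled as beta_tl = beta_e + delta, where the
cross-population offset delta is assumed sparse and is estimated on the
target summary statistics with target-ancestry LD by maximizing

    2 (r_a - R_a beta_e)' delta - delta' R_a delta - 2 lambda_d ||delta||_1,

i.e. the same lasso objective with the correlation vector residualized by
the auxiliary fit. Both tuning selections use pseudovalidation, so no
individual-level phenotype data are required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genio import GenotypePanel, LDBlocks, SummaryStats, harmonize_variants
from .lassosum import (
    AllZeroPathError,
    BlockLD,
    EffectPath,
    LassosumConfig,
    compute_block_ld,
    ensure_r,
    fit_lassosum_path,
    select_by_validation,
)

logger = logging.getLogger(__name__)


@dataclass
class TransferFit:
    """Result of the transfer fit: auxiliary effects, offset, and their sum."""

    beta_e: np.ndarray
    delta: np.ndarray
    beta_tl: np.ndarray
    selected_aux: tuple | None  # (s, lambda) of the auxiliary fit
    selected_delta: tuple | None  # (s, lambda_delta) of the offset fit
    sparsity_report: dict
    aux_path: EffectPath | None = None
    delta_path: EffectPath | None = None

    @property
    def lambda_delta(self) -> float | None:
        return None if self.selected_delta is None else self.selected_delta[1]


def adjust_correlation(
    r_a: np.ndarray, beta_e: np.ndarray, blockld_a: BlockLD
) -> np.ndarray:
    """Residualize target correlations by the auxiliary effects: r_a - R_a beta_e.

    Computed blockwise with the target-ancestry LD; variants outside every
    block keep r_adj = r_a - s-free diagonal contribution of zero, i.e.
    r_a - beta_e there (identity LD).
    """
    r_a = np.asarray(r_a, dtype=float)
    beta_e = np.asarray(beta_e, dtype=float)
    if r_a.shape != beta_e.shape:
        raise ValueError("r_a and beta_e must have the same length")
    if r_a.size != blockld_a.n_variants:
        raise ValueError("vectors do not match the LD panel dimension")
    r_adj = r_a - beta_e  # identity fallback for unassigned variants
    for R, ix in zip(blockld_a.matrices, blockld_a.variant_indices):
        r_adj[ix] = r_a[ix] - R @ beta_e[ix]
    return r_adj


def fit_delta_path(
    r_adj: np.ndarray,
    blockld_a: BlockLD,
    config: LassosumConfig | None = None,
) -> EffectPath:
    """Lasso path for the offset delta on the residualized correlations.

    Identical solver contract to the auxiliary fit; pseudovalidation runs
    on (r_adj, R_a) and an all-zero selection is legitimate (it means the
    auxiliary effects already explain the target signal).
    """
    return fit_lassosum_path(
        stats=None,
        blockld=blockld_a,
        config=config,
        r=np.asarray(r_adj, dtype=float),
        allow_all_zero=True,
    )


def combine_effects(beta_e: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """beta_tl = beta_e + delta (elementwise)."""
    beta_e = np.asarray(beta_e, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if beta_e.shape != delta.shape:
        raise ValueError("beta_e and delta must have the same length")
    return beta_e + delta


def delta_sparsity_diagnostic(delta: np.ndarray, q_list=(0.0, 0.5, 1.0)) -> dict:
    """L_q "norms" of the offset for q in [0, 1].

    q = 0 gives the support size; q in (0, 1] gives sum_i |delta_i|^q.
    These diagnose how well the sparse-offset assumption holds; no
    threshold is applied.
    """
    delta = np.asarray(delta, dtype=float)
    report = {}
    for q in q_list:
        q = float(q)
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"q must be in [0, 1], got {q}")
        if q == 0.0:
            report[q] = int(np.count_nonzero(delta))
        else:
            report[q] = float(np.sum(np.abs(delta) ** q))
    return report


def tl_multi(
    stats_target: SummaryStats,
    stats_aux: SummaryStats,
    panel_aux_ld: GenotypePanel,
    panel_target_ld: GenotypePanel,
    blocks_aux: LDBlocks,
    blocks_target: LDBlocks,
    config: LassosumConfig | None = None,
    harmonize: bool = True,
    validation_panel: GenotypePanel | None = None,
    validation_phenotype: np.ndarray | None = None,
    aux_validation_panel: GenotypePanel | None = None,
    aux_validation_phenotype: np.ndarray | None = None,
    blockld_aux: BlockLD | None = None,
    blockld_target: BlockLD | None = None,
) -> TransferFit:
    """Run the full transfer pipeline on harmonized summary statistics.

    Steps: (1) fit the auxiliary lasso path with auxiliary-ancestry LD and
    select beta_e by pseudovalidation; (2) residualize the target
    correlations with target-ancestry LD; (3) fit and select the offset
    delta; (4) combine. When the auxiliary path is entirely zero the
    method degenerates gracefully to a target-only lasso (beta_e = 0).

    Tuning defaults to pseudovalidation (summary data only). When a
    phenotyped target-ancestry ``validation_panel`` is supplied, the
    offset penalty is selected by cross-validated R^2 of the combined
    predictor beta_e + delta on that panel, and the auxiliary grid point
    by cross-validated R^2 on ``aux_validation_panel`` (a phenotyped
    auxiliary-ancestry panel, keeping beta_e the ancestry-matched optimal
    PRS) when one is given, else on the target validation panel. These
    validation modes are recommended when individual-level data exist:
    pseudovalidation reuses the noisy GWAS correlations and overfits
    toward dense solutions when the GWAS sample is small.

    ``harmonize=False`` skips variant alignment for inputs already known
    to share one variant order (e.g. simulated data).
    """
    config = config or LassosumConfig()
    if harmonize:
        (stats_target, stats_aux), (panel_aux_ld, panel_target_ld) = harmonize_variants(
            [stats_target, stats_aux], [panel_aux_ld, panel_target_ld]
        )
    if stats_target.n_variants == 0:
        raise ValueError("no variants left after harmonization")

    blockld_e = blockld_aux or compute_block_ld(panel_aux_ld, blocks_aux)
    blockld_a = blockld_target or compute_block_ld(panel_target_ld, blocks_target)

    if validation_panel is not None and validation_phenotype is None:
        validation_phenotype = validation_panel.phenotype
    if validation_panel is not None and validation_phenotype is None:
        raise ValueError("validation panel given without a phenotype")

    try:
        aux_path = fit_lassosum_path(
            stats_aux,
            blockld_e,
            config=config,
            pseudovalidation=validation_panel is None,
        )
        if validation_panel is not None:
            if aux_validation_panel is not None:
                if aux_validation_phenotype is None:
                    aux_validation_phenotype = aux_validation_panel.phenotype
                select_by_validation(
                    aux_path, aux_validation_panel, aux_validation_phenotype
                )
            else:
                select_by_validation(aux_path, validation_panel, validation_phenotype)
            if not np.any(aux_path.beta_opt):
                raise AllZeroPathError("validation selected an all-zero auxiliary fit")
        beta_e = aux_path.beta_opt
        selected_aux = aux_path.selected
    except AllZeroPathError:
        logger.warning(
            "auxiliary lasso path is identically zero; transfer degenerates "
            "to a target-only fit"
        )
        aux_path = None
        beta_e = np.zeros(stats_aux.n_variants)
        selected_aux = None

    r_a = ensure_r(stats_target)
    r_adj = adjust_correlation(r_a, beta_e, blockld_a)
    delta_path = fit_delta_path(r_adj, blockld_a, config=config)
    if validation_panel is not None:
        select_by_validation(
            delta_path, validation_panel, validation_phenotype, offset_beta=beta_e
        )
    delta = delta_path.beta_opt
    beta_tl = combine_effects(beta_e, delta)

    return TransferFit(
        beta_e=beta_e,
        delta=delta,
        beta_tl=beta_tl,
        selected_aux=selected_aux,
        selected_delta=delta_path.selected,
        sparsity_report=delta_sparsity_diagnostic(delta),
        aux_path=aux_path,
        delta_path=delta_path,
    )
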