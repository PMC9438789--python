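"""Two-population synthetic data for cross-ancestry PRS methods.

Emulates the standard simulation design for transfer-learning PRS: two
populations share a common set of causal variants whose per-population
effect sizes are drawn from a bivariate normal with cross-population
correlation rho and per-variant variance h^2/m (m = number of causal
variants), so the genetic variance sums to the SNP-heritability h^2.
Quantitative phenotypes follow y = Z beta + eps on standardized
genotypes Z with eps ~ N(0, 1 - h^2). Genotypes have block LD: within
each block, haplotypes come from a latent AR(1) Gaussian copula
(adjacent-variant latent correlation ``within_block_corr``, decaying
geometrically with distance) thresholded at the allele frequency, and
blocks are mutually independent. The two populations share allele
frequencies and variant identities but differ in LD decay and in their
random draws, mimicking ancestry-specific LD.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genio import GenotypePanel, LDBlocks
from .lassosum import (
    LassosumConfig,
    compute_block_ld,
    ensure_r,
    fit_lassosum_path,
    score_prs,
)

logger = logging.getLogger(__name__)

# spacing between adjacent simulated variants, in base pairs
_VARIANT_SPACING = 5_000


@dataclass
class SimulationConfig:
    """Generative parameters of the two-population simulation.

    Defaults follow the standard design for this problem: SNP-heritability
    h^2 = 0.5, 1.5% of variants causal, cross-population effect
    correlation rho = 0.4, and a 25:1 auxiliary-to-target sample-size
    ratio. Panel sizes (p, n) are desk scale.
    """

    h2: float = 0.5
    rho: float = 0.4
    causal_fraction: float = 0.015
    n_target: int = 1_000
    n_aux: int = 25_000
    p: int = 2_000
    n_blocks: int = 20
    within_block_corr: float = 0.9
    within_block_corr_aux: float = 0.85
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [-1, 1]")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must be in (0, 1]")
        if min(self.n_target, self.n_aux, self.p, self.n_blocks) < 1:
            raise ValueError("counts must be positive")

    @property
    def m_causal(self) -> int:
        return max(1, round(self.causal_fraction * self.p))


@dataclass
class TruthSet:
    """Ground truth of one replicate: causal set and true effect vectors."""

    causal_indices: np.ndarray
    beta_true_target: np.ndarray
    beta_true_aux: np.ndarray
    phenotypes: dict = field(default_factory=dict)


def _rng(config: SimulationConfig, *scope) -> np.random.Generator:
    """Independent, reproducible stream for a named scope of the simulation."""
    digest = hashlib.sha256("/".join(str(s) for s in scope).encode()).digest()
    tag = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), tag]))


def _block_sizes(p: int, n_blocks: int) -> np.ndarray:
    sizes = np.full(n_blocks, p // n_blocks, dtype=np.int64)
    sizes[: p % n_blocks] += 1
    return sizes


def make_ld_blocks(config: SimulationConfig) -> LDBlocks:
    """Block definitions matching the generator's layout (one chromosome).

    Variant j sits at 1-based position (j+1) * spacing; block boundaries
    are placed between blocks so every variant maps to its generative
    block under the 0-based half-open convention.
    """
    sizes = _block_sizes(config.p, config.n_blocks)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    intervals = pd.DataFrame(
        {
            "chrom": "1",
            "start": bounds[:-1] * _VARIANT_SPACING,
            "end": bounds[1:] * _VARIANT_SPACING,
        }
    )
    return LDBlocks(intervals=intervals)


def _variant_table(config: SimulationConfig) -> pd.DataFrame:
    idx = np.arange(config.p)
    return pd.DataFrame(
        {
            "id": [f"snp{j}" for j in idx],
            "chrom": "1",
            "pos": (idx + 1) * _VARIANT_SPACING,
            "a1": "A",
            "a2": "C",
        }
    )


def _draw_mafs(config: SimulationConfig) -> np.ndarray:
    lo, hi = config.maf_range
    return _rng(config, "maf").uniform(lo, hi, size=config.p)


def simulate_genotype_panel(
    config: SimulationConfig,
    population_tag: str,
    n: int | None = None,
    seed_offset: int = 0,
) -> GenotypePanel:
    """Draw an n x p dosage panel for one population.

    Dosages are Binomial(2, maf) marginally; within-block LD comes from
    an AR(1) latent Gaussian per haplotype, with decay parameter chosen
    by ``population_tag`` ("target" vs any other tag, e.g. "aux").
    ``seed_offset`` distinguishes panels of the same population (train /
    test / reference) within one replicate.
    """
    if n is None:
        n = config.n_target if population_tag == "target" else config.n_aux
    phi = (
        config.within_block_corr
        if population_tag == "target"
        else config.within_block_corr_aux
    )
    mafs = _draw_mafs(config)
    thresholds = sps.norm.ppf(mafs)
    rng = _rng(config, "panel", population_tag, seed_offset)

    sizes = _block_sizes(config.p, config.n_blocks)
    dosages = np.empty((n, config.p), dtype=np.int8)
    col = 0
    scale = np.sqrt(max(1.0 - phi * phi, 0.0))
    for bs in sizes:
        latent = rng.standard_normal((2 * n, bs))
        for j in range(1, bs):
            latent[:, j] = phi * latent[:, j - 1] + scale * latent[:, j]
        haplo = latent < thresholds[col : col + bs]
        dosages[:, col : col + bs] = (
            haplo.reshape(n, 2, bs).sum(axis=1).astype(np.int8)
        )
        col += bs
    return GenotypePanel(
        dosages=dosages,
        variants=_variant_table(config),
        sample_ids=pd.DataFrame(
            {
                "fid": [f"{population_tag}{i}" for i in range(n)],
                "iid": [f"{population_tag}{i}" for i in range(n)],
            }
        ),
    )


def simulate_effect_sizes(config: SimulationConfig) -> TruthSet:
    """Shared causal variants with bivariate-normal per-population effects.

    m = round(causal_fraction * p) causal indices are drawn uniformly;
    each causal variant's (target, auxiliary) effect pair comes from a
    zero-mean bivariate normal with variances h^2/m and correlation rho.
    Non-causal effects are exactly zero.
    """
    m = config.m_causal
    if m > config.p:
        raise ValueError("more causal variants than variants")
    rng = _rng(config, "effects")
    causal = np.sort(rng.choice(config.p, size=m, replace=False))
    var = config.h2 / m
    cov = var * np.array([[1.0, config.rho], [config.rho, 1.0]])
    draws = rng.multivariate_normal(np.zeros(2), cov, size=m, method="svd")
    beta_t = np.zeros(config.p)
    beta_a = np.zeros(config.p)
    beta_t[causal] = draws[:, 0]
    beta_a[causal] = draws[:, 1]
    return TruthSet(
        causal_indices=causal, beta_true_target=beta_t, beta_true_aux=beta_a
    )


def simulate_phenotype(
    panel: GenotypePanel,
    beta_true: np.ndarray,
    h2: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """y = Z beta + eps with eps ~ N(0, 1 - h^2) on standardized genotypes."""
    rng = rng or np.random.default_rng()
    Z = panel.standardized()
    genetic = Z @ np.asarray(beta_true, dtype=float)
    noise_sd = np.sqrt(max(1.0 - h2, 0.0))
    return genetic + rng.normal(0.0, noise_sd, size=panel.n_samples) if noise_sd > 0 else genetic


def liability_to_binary(
    y: np.ndarray, prevalence: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Threshold a quantitative liability into 0/1 at a given prevalence."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    cut = np.quantile(y, 1.0 - prevalence)
    return (y > cut).astype(int)


def run_gwas(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
):
    """Per-variant OLS of the phenotype on each standardized dosage column.

    Covariates (plus an intercept) are residualized out of both phenotype
    and genotypes once and reused across variants; beta, SE, t and the
    two-sided p-value use the residual degrees of freedom n - k - 2
    (intercept + k covariates + the variant). Zero-variance variants get
    beta 0 and infinite SE.
    """
    from .genio import SummaryStats

    y = np.asarray(phenotype, dtype=float)
    n = panel.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length must equal the sample count")
    C = np.ones((n, 1))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            raise ValueError("covariate rows must equal the sample count")
        C = np.column_stack([C, covariates])
    k = C.shape[1]
    dof = n - k - 1
    if dof < 1:
        raise ValueError("not enough samples for the covariate model")

    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    Z = panel.standardized()
    Z_res = Z - Q @ (Q.T @ Z)

    sxx = np.einsum("ij,ij->j", Z_res, Z_res)
    sxy = Z_res.T @ y_res
    syy = float(y_res @ y_res)
    nonconst = sxx > 0

    beta = np.zeros(panel.n_variants)
    beta[nonconst] = sxy[nonconst] / sxx[nonconst]
    rss = syy - beta * sxy
    rss = np.maximum(rss, 0.0)
    se = np.full(panel.n_variants, np.inf)
    se[nonconst] = np.sqrt(rss[nonconst] / dof / sxx[nonconst])
    se[se == 0] = np.finfo(float).tiny  # perfect fit: avoid zero SE
    tstat = np.where(np.isfinite(se), beta / se, 0.0)
    pval = np.clip(2 * sps.t.sf(np.abs(tstat), dof), np.nextafter(0, 1), 1.0)

    return SummaryStats(
        variants=panel.variants,
        beta=beta,
        se=np.where(np.isfinite(se), se, np.finfo(float).max),
        pval=pval,
        n=np.full(panel.n_variants, n, dtype=np.int64),
        tstat=tstat,
    )


# ---------------------------------------------------------------------------
# Replicate pipeline and full study
# ---------------------------------------------------------------------------


def run_replicate(
    config: SimulationConfig,
    replicate: int = 0,
    n_test: int = 1_000,
    n_validation: int = 1_000,
    methods=("lassosum_target", "lassosum_aux", "meta", "tlmulti"),
    lasso_config: LassosumConfig | None = None,
    tuning: str = "validation",
    pt_kwargs: dict | None = None,
) -> dict:
    """One replicate: simulate both populations, run methods, score R^2.

    Generates training panels for both populations plus fresh target
    validation and test panels, simulates phenotypes from the shared
    truth, computes GWAS summary statistics, then fits the requested
    methods and returns the test-set R^2 per method (keys as in
    ``methods``). With ``tuning="validation"`` (default) every method's
    tuning parameters are selected by 10-fold cross-validated R^2 on the
    held-out validation panel — the protocol used with individual-level
    validation data; ``tuning="pseudovalidation"`` selects from summary
    data alone. The test panel is used only for the reported accuracy.
    """
    from .baselines import meta_combine, pt_multi
    from .evaluate import r2_metric
    from .lassosum import select_by_validation
    from .transfer import tl_multi

    if tuning not in ("validation", "pseudovalidation"):
        raise ValueError("tuning must be 'validation' or 'pseudovalidation'")
    cfg = SimulationConfig(**{**config.__dict__, "seed": _replicate_seed(config, replicate)})
    lasso_config = lasso_config or LassosumConfig()

    truth = simulate_effect_sizes(cfg)
    panel_t = simulate_genotype_panel(cfg, "target")
    panel_a = simulate_genotype_panel(cfg, "aux")
    panel_test = simulate_genotype_panel(cfg, "target", n=n_test, seed_offset=1)
    panel_val = simulate_genotype_panel(cfg, "target", n=n_validation, seed_offset=2)
    panel_val_aux = simulate_genotype_panel(cfg, "aux", n=n_validation, seed_offset=3)

    rng_y = _rng(cfg, "phenotypes")
    y_t = simulate_phenotype(panel_t, truth.beta_true_target, cfg.h2, rng_y)
    y_a = simulate_phenotype(panel_a, truth.beta_true_aux, cfg.h2, rng_y)
    y_test = simulate_phenotype(panel_test, truth.beta_true_target, cfg.h2, rng_y)
    y_val = simulate_phenotype(panel_val, truth.beta_true_target, cfg.h2, rng_y)
    y_val_aux = simulate_phenotype(panel_val_aux, truth.beta_true_aux, cfg.h2, rng_y)
    truth.phenotypes = {"target": y_t, "aux": y_a, "test": y_test, "validation": y_val}

    stats_t = run_gwas(panel_t, y_t)
    stats_a = run_gwas(panel_a, y_a)

    blocks = make_ld_blocks(cfg)
    blockld_t = compute_block_ld(panel_t, blocks)
    blockld_a = compute_block_ld(panel_a, blocks)

    validate = tuning == "validation"

    def _select(path):
        if validate:
            select_by_validation(path, panel_val, y_val)
        return path.beta_opt

    results: dict = {}
    betas: dict = {}
    for method in methods:
        try:
            if method == "lassosum_target":
                path = fit_lassosum_path(stats_t, blockld_t, config=lasso_config)
                betas[method] = _select(path)
            elif method == "lassosum_aux":
                path = fit_lassosum_path(stats_a, blockld_a, config=lasso_config)
                betas[method] = _select(path)
            elif method == "meta":
                meta_stats = meta_combine(stats_t, stats_a)
                # auxiliary samples dominate the combined GWAS, so use their LD
                path = fit_lassosum_path(meta_stats, blockld_a, config=lasso_config)
                betas[method] = _select(path)
            elif method == "tlmulti":
                fit = tl_multi(
                    stats_t,
                    stats_a,
                    panel_aux_ld=panel_a,
                    panel_target_ld=panel_t,
                    blocks_aux=blocks,
                    blocks_target=blocks,
                    config=lasso_config,
                    harmonize=False,
                    validation_panel=panel_val if validate else None,
                    validation_phenotype=y_val if validate else None,
                    aux_validation_panel=panel_val_aux if validate else None,
                    aux_validation_phenotype=y_val_aux if validate else None,
                    blockld_aux=blockld_a,
                    blockld_target=blockld_t,
                )
                betas[method] = fit.beta_tl
            elif method == "ptmulti":
                panel_val = GenotypePanel(
                    dosages=panel_t.dosages,
                    variants=panel_t.variants,
                    sample_ids=panel_t.sample_ids,
                    phenotype=y_t,
                )
                ptfit = pt_multi(
                    [stats_t, stats_a], panel_val, **(pt_kwargs or {})
                )
                # re-score the weighted combination on the test panel
                prs_test = _pt_score_test(ptfit, [stats_t, stats_a], panel_test, panel_val)
                results[method] = r2_metric(prs_test, y_test)
                continue
            else:
                raise ValueError(f"unknown method '{method}'")
            prs = score_prs(panel_test, betas[method])
            if np.std(prs) == 0:
                results[method] = 0.0
            else:
                results[method] = r2_metric(prs, y_test)
        except Exception as exc:  # single-method failure: log, continue
            logger.warning("method %s failed in replicate %d: %s", method, replicate, exc)
            results[method] = np.nan
    return results


def _pt_score_test(ptfit, stats_list, panel_test, panel_val):
    """Apply a fitted PT-Multi model to a new panel."""
    from .baselines import clump  # clumped sets were derived on panel_val

    prs_cols = []
    for thr, stats in zip(ptfit.thresholds, stats_list):
        cl = clump(stats, panel_val)
        sel = np.array(
            [j for j in cl.index_variants if stats.pval[j] <= thr], dtype=np.int64
        )
        beta = np.zeros(stats.n_variants)
        if sel.size:
            beta[sel] = stats.beta[sel]
        prs_cols.append(score_prs(panel_test, beta))
    return ptfit.intercept + np.column_stack(prs_cols) @ ptfit.weights


def realized_heritability(
    config: SimulationConfig, replicates: int = 20, population_tag: str = "target"
) -> np.ndarray:
    """Per-replicate realized SNP-heritability var(Z beta) / var(y).

    For each replicate a fresh panel, causal-effect draw and phenotype are
    generated from ``config`` (with replicate-specific seeds) and the
    ratio of genetic to total phenotypic variance is computed; its mean
    over replicates estimates the generator's heritability contract.
    """
    ratios = np.empty(replicates)
    for rep in range(replicates):
        cfg = SimulationConfig(
            **{**config.__dict__, "seed": _replicate_seed(config, rep)}
        )
        truth = simulate_effect_sizes(cfg)
        panel = simulate_genotype_panel(cfg, population_tag)
        beta = (
            truth.beta_true_target
            if population_tag == "target"
            else truth.beta_true_aux
        )
        genetic = panel.standardized() @ beta
        y = genetic + _rng(cfg, "herit-noise").normal(
            0.0, np.sqrt(max(1.0 - cfg.h2, 0.0)), size=panel.n_samples
        )
        ratios[rep] = np.var(genetic) / np.var(y)
    return ratios


def _replicate_seed(config: SimulationConfig, replicate: int) -> int:
    digest = hashlib.sha256(
        f"{config.seed}/rep/{replicate}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def simulation_study(
    scenarios,
    replicates: int = 20,
    seed: int = 0,
    n_test: int = 1_000,
    n_validation: int = 1_000,
    methods=("lassosum_target", "lassosum_aux", "meta", "tlmulti"),
    lasso_config: LassosumConfig | None = None,
    tuning: str = "validation",
) -> pd.DataFrame:
    """Run the replicate pipeline over a scenario grid.

    ``scenarios`` is an iterable of dicts of SimulationConfig overrides
    (e.g. ``{"rho": 0.4, "causal_fraction": 0.015}``). Returns a tidy
    DataFrame with one row per scenario x method carrying the mean R^2
    over replicates and the upper bound of its 95% confidence interval,
    plus the per-replicate values.
    """
    rows = []
    for si, overrides in enumerate(scenarios):
        cfg = SimulationConfig(**{"seed": seed, **overrides})
        per_method: dict = {m: [] for m in methods}
        for rep in range(replicates):
            res = run_replicate(
                cfg,
                replicate=rep,
                n_test=n_test,
                n_validation=n_validation,
                methods=methods,
                lasso_config=lasso_config,
                tuning=tuning,
            )
            for m in methods:
                per_method[m].append(res[m])
        for m in methods:
            vals = np.asarray(per_method[m], dtype=float)
            ok = vals[~np.isnan(vals)]
            mean = float(ok.mean()) if ok.size else np.nan
            sem = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else 0.0
            rows.append(
                {
                    **{k: v for k, v in overrides.items()},
                    "scenario": si,
                    "method": m,
                    "mean_r2": mean,
                    "ci95_upper": mean + 1.96 * sem,
                    "replicate_r2": ok.tolist(),
                }
            )
    return pd.DataFrame(rows)
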