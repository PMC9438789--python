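# Methods

## Summary-statistics lasso

The core estimator maximizes, per LD block,
`2 rᵀβ − βᵀR_sβ − 2λ‖β‖₁` with `R_s = (1−s)R + sI`. This is the dual of
an L1-penalized regression on standardized individual-level data: with
`r = Xᵀy/n` and `R = XᵀX/n`, the objective equals `(yᵀy − ‖y − Xβ‖²)/n −
2λ‖β‖₁` up to constants, so it can be optimized from summary data plus a
reference panel alone. The shrinkage `s` keeps `R_s` positive definite
when the reference panel is small or the block is large; `s = 1`
decouples the variants entirely (pure soft-thresholding of `r`).

SNP-wise correlations are recovered from GWAS t-statistics as
`r = t/√(n − 1 + t²)` and clipped to ±0.999. Blocks are treated as
independent, which matches how LD-block files (e.g. ldetect-style BED
intervals) are meant to be used; a variant falling in no block is
treated as its own singleton block.

Solver: cyclic coordinate descent,
`β_j ← soft(r_j − Σ_{k≠j}(R_s)_{jk}β_k, λ)/(R_s)_{jj}`, warm-started
along the descending λ grid. Each coordinate update solves its
one-dimensional subproblem exactly, so the objective is monotone
non-decreasing across sweeps; convergence is declared when the largest
coefficient change in a sweep falls below `tol` (default 1e−4, max 1000
sweeps; the tests tighten this to 1e−10/5·10⁴ when comparing against an
independent convex solver to 1e−6). The inner loop is numba-compiled
with a pure-Python fallback.

Defaults: `s_grid = {0.2, 0.5, 0.9, 1.0}` and 20 log-spaced penalties in
[0.001, 0.1]. Neither grid is canonical; these are the common choices
for this estimator family and both are configurable (`LassosumConfig`,
or a YAML file for the CLI).

## Tuning-parameter selection

Two modes:

* **Pseudovalidation** (summary data only): score each grid point by the
  projected correlation `rᵀβ̂ / √(β̂ᵀR_sβ̂)`, a scale-invariant estimate
  of the correlation between the PRS and the phenotype. Ties break
  toward larger λ (the sparser model); an all-zero path is an error
  unless explicitly allowed (see the offset step below). Caveat: the
  score reuses the same noisy `r` that the fit consumed. When the GWAS
  is small relative to the variant count the noise term `‖r_noise‖² ≈
  p/n` dominates and the score drifts monotonically toward the densest
  grid point; pseudovalidation is then anti-conservative. This is
  intrinsic to phenotype-free selection, not a solver artifact.
* **Validation selection** (`select_by_validation`): mean 10-fold
  cross-validated R² of the PRS on a phenotyped individual-level panel,
  seeded folds. This is the mode the simulation study uses for every
  method, reflecting the standard protocol when a validation cohort
  exists. An `offset_beta` argument lets the offset step select its
  penalty by the accuracy of the *combined* predictor.

## Transfer construction

`β_tl = β_e + δ`. Steps: (1) fit the auxiliary lasso path with
auxiliary-ancestry LD and select `β_e` — by pseudovalidation, or, in
validation mode, by cross-validated R² on an auxiliary-ancestry
validation panel so that `β_e` remains the ancestry-matched optimum;
(2) residualize the target correlations blockwise, `r_adj = r_a −
R_aβ_e`, using target-ancestry LD; (3) fit the offset path on `r_adj`
(identical objective and solver with `r := r_adj`) and select `λ_δ`;
(4) add. The δ objective follows from expanding `‖y_a − X_a(β_e+δ)‖²`
on standardized data, which makes the offset step exactly a lasso on
residualized correlations — the form consistent with the model
`β_a = β_e + δ` — and lets one verified solver cover both steps.

Degenerate cases are defined to behave sensibly: an all-zero auxiliary
path reduces the method to the target-only lasso (`β_e = 0`), and an
all-zero offset is a legitimate selection (it means the auxiliary fit
already explains the target correlations), so the δ-step's
pseudovalidation permits the zero vector while the standalone API
raises on an all-zero path by default.

The sparsity of δ is the method's key assumption (most causal variants
shared, population differences concentrated in few variants). The
`L_q` diagnostics (`q ∈ {0, 0.5, 1}`) of the fitted offset are reported
raw; no threshold is applied because none is established — users judge
transferability against the scale of `β_e`.

## Comparators

* **Meta-analysis**: fixed-effect inverse-variance combination on the
  harmonized variant intersection; downstream lasso uses the LD of the
  population dominating the combined sample (auxiliary by default).
* **PT-Multi**: per population, greedy p-value-ordered clumping
  (reference-panel r² threshold 0.1, 250 kb window — the window is a
  conventional default, the threshold the standard choice for this
  procedure) followed by p-value thresholding over the grid {1, 0.3,
  0.1, 3e−2, 1e−2, 3e−3, 1e−3, 3e−4, 1e−4}, threshold chosen by 10-fold
  CV (R², or logistic-regression AUC for binary traits); the
  per-population scores are combined by least squares / logistic
  regression with intercept. Constant score columns get weight zero.

## Variant harmonization and QC

Inputs are aligned on shared variant ids in the first input's order.
Swapped alleles (including swapped-on-the-opposite-strand) sign-flip
`beta`, `t` and `r` and complement the panel dosages (2 − dosage);
strand-ambiguous palindromic variants (A/T, C/G) are dropped — the
conservative choice, since strand cannot be resolved without frequency
heuristics; irreconcilable alleles are dropped. Positions are 1-based
(.bim convention); LD-block files are 0-based half-open BED, and a
variant at position p belongs to [start, end) iff start < p ≤ end.

QC removes variants with minor allele frequency ≤ 0.01 or
Hardy–Weinberg exact-test p < 1e−5 (the standard exact test summing
probabilities of configurations at most as probable as observed, not
mid-p). Missing genotypes are mean-imputed per variant before
standardization, preserving column means and keeping LD computation
simple.

## Synthetic data generator

The simulator emulates the two-population design used to study
cross-ancestry PRS: h² = 0.5; a shared causal set of m =
round(causal_fraction·p) variants (fractions 1–5%, default 1.5%);
per-population effects for each causal variant drawn from a bivariate
normal with variances h²/m (so genetic variance sums to h²) and
cross-population correlation ρ ∈ {0.2, 0.4, 0.6, 0.8} (default 0.4);
phenotypes y = Zβ + ε with ε ~ N(0, 1 − h²) on standardized genotypes;
25:1 auxiliary:target sample ratio by default. GWAS summary statistics
come from per-variant OLS on standardized dosages with optional
covariates (residualized once and reused), t-distribution p-values with
the correct residual degrees of freedom.

Genotypes: dosages are Binomial(2, maf) marginally (maf ~ U(0.05, 0.5),
shared across populations); within-block LD comes from a latent AR(1)
Gaussian copula per haplotype — adjacent latent correlation 0.9 for the
target population and 0.85 for the auxiliary one, decaying
geometrically — and blocks (default 20 blocks of 100 variants, one
synthetic chromosome, 5 kb spacing) are independent. This preserves the
features the methods rely on (block LD, ancestry-specific LD, shared
causal architecture) but not real human LD: no MAF–LD coupling, no
long-range LD, no population-specific allele frequencies, no
relatedness. Passing tests therefore demonstrate correctness of the
estimators under the generative model, not real-data performance. A
liability-threshold option converts quantitative phenotypes to 0/1 at a
configured prevalence for exercising the AUC/prevalence machinery.

All randomness flows through named, hashed seed streams derived from a
single integer seed: panels, effects and phenotypes are reproducible
individually and the whole study is deterministic end to end.

## Simulation study scale

The replicate pipeline runs at desk scale: p = 2,000 variants,
n_target = 400–1,000, n_aux = 10,000–25,000, fresh validation panels
(n = 1,000 each for target and auxiliary ancestry) for tuning and a
fresh test panel (n = 1,000) for accuracy, 20 replicates per scenario.
These sizes keep every other structural feature of the full-scale
design (block LD, 25:1 imbalance, shared causal sets). One consequence
of desk scale is a relatively *informative* target GWAS (p/n ≈ 5
against ≈ 20 at full scale), which narrows the transfer method's margin
over the target-only lasso: the ordering checks assert means over 20
replicates, not per-replicate dominance.

## Numerical choices

Tolerances: coordinate-descent tol 1e−4 on the max coefficient change
(1e−10 in oracle tests); correlations clipped to ±0.999; SEs of
monomorphic variants set to the float maximum with beta 0. Tie-breaks:
pseudovalidation and validation selection prefer larger λ on ties;
clumping visits variants by ascending p with ties broken by position
then id; prevalence quantile bins take ⌈qn⌉ samples with stable-sort
tie-breaking. Degenerate inputs: constant genotype columns standardize
to zero and get zero LD weight; single-class labels are an error for
AUC but not for prevalence tables; fold changes with an empty-case
bottom bin are reported as undefined (None) rather than infinite.

## Known limitations

* Pseudovalidation overfits for small GWAS (see above); prefer
  validation selection whenever individual-level data exist.
* One auxiliary population only; no cross-trait transfer.
* The meta-analysis path handles the variant intersection only.
* LD blocks are taken as given; no block estimation is provided.
* X chromosome, imputation quality filtering and VCF/BGEN input are out
  of scope.
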