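"""Blockwise lasso solver, pseudovalidation and PRS scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlprs.lassosum import (
    AllZeroPathError,
    BlockLD,
    LassosumConfig,
    block_coordinate_descent,
    compute_block_ld,
    ensure_r,
    fit_lassosum_path,
    lasso_objective,
    pseudovalidate,
    score_prs,
    select_by_validation,
    soft_threshold,
    tstat_to_correlation,
)
from tlprs.genio import LDBlocks

from conftest import make_panel, make_stats, make_variants, random_ld_instance

TIGHT = LassosumConfig(max_iter=20_000, tol=1e-12)


def oracle_lasso(r, R_s, lam):
    """Independent convex solver for max 2r'b - b'R_s b - 2 lam ||b||_1.

    Split b = u - v with u, v >= 0 and minimize the smooth bound-constrained
    QP with L-BFGS-B; never touches the coordinate-descent code path.
    """
    from scipy.optimize import minimize

    p = r.size

    def fg(x):
        u, v = x[:p], x[p:]
        b = u - v
        Rb = R_s @ b
        f = b @ Rb - 2 * r @ b + 2 * lam * (u.sum() + v.sum())
        g = 2 * Rb - 2 * r + 2 * lam
        return f, np.concatenate([g, -2 * Rb + 2 * r + 2 * lam])

    res = minimize(
        fg,
        np.zeros(2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * 2 * p,
        options={"maxiter": 50_000, "ftol": 1e-20, "gtol": 1e-12},
    )
    return res.x[:p] - res.x[p:]


# --- correlation conversion -------------------------------------------------


def test_tstat_to_correlation_closed_form():
    assert tstat_to_correlation(0.0, 10) == 0.0
    assert tstat_to_correlation(2.0, 101) == pytest.approx(2 / np.sqrt(104))
    r3, r6 = tstat_to_correlation([1e3, 1e6], [100, 100])
    assert 0 < r3 < r6 < 1  # monotone in t, bounded by 1
    with pytest.raises(ValueError):
        tstat_to_correlation(1.0, 1)


# --- soft thresholding ------------------------------------------------------


def test_soft_threshold_examples():
    assert soft_threshold(0.5, 0.4) == pytest.approx(0.1)
    assert soft_threshold(-0.5, 0.4) == pytest.approx(-0.1)
    assert soft_threshold(0.3, 0.4) == 0.0
    with pytest.raises(ValueError):
        soft_threshold(0.5, -0.1)


@given(st.floats(-5, 5), st.floats(0, 5))
@settings(deadline=None, max_examples=50)
def test_soft_threshold_odd_symmetry(x, lam):
    assert soft_threshold(-x, lam) == pytest.approx(-soft_threshold(x, lam))


# --- block coordinate descent ----------------------------------------------


def test_cd_identity_ld_is_soft_thresholding():
    beta = block_coordinate_descent(
        np.array([0.5, 0.3]), np.eye(2), s=1.0, lam=0.4, config=TIGHT
    )
    np.testing.assert_allclose(beta, [0.1, 0.0], atol=1e-10)


def test_cd_lambda_zero_solves_linear_system():
    R = np.array([[1.0, 0.5], [0.5, 1.0]])
    r = np.array([0.5, 0.3])
    # no LD shrinkage: solve with R as given
    beta = block_coordinate_descent(r, R, s=0.0, lam=1e-12, config=TIGHT)
    np.testing.assert_allclose(beta, np.linalg.solve(R, r), atol=1e-6)
    np.testing.assert_allclose(beta, [0.46667, 0.06667], atol=1e-4)


def test_cd_full_shrinkage_returns_zero(rng):
    r, blockld = random_ld_instance(rng, p=10, n_blocks=1)
    lam = np.abs(r).max() + 0.01
    beta = block_coordinate_descent(
        r, blockld.matrices[0], s=1.0, lam=lam, config=TIGHT
    )
    assert np.all(beta == 0)


def test_cd_objective_nondecreasing_over_sweeps(rng):
    r, blockld = random_ld_instance(rng, p=15, n_blocks=1)
    R = blockld.matrices[0]
    import warnings

    prev = lasso_objective(np.zeros(15), r, blockld, 0.5, 0.01)
    beta = np.zeros(15)
    one_sweep = LassosumConfig(max_iter=1, tol=1e-300)
    for _ in range(30):  # one sweep at a time
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            beta = block_coordinate_descent(r, R, 0.5, 0.01, init=beta, config=one_sweep)
        obj = lasso_objective(beta, r, blockld, 0.5, 0.01)
        assert obj >= prev - 1e-12
        prev = obj


def test_cd_matches_oracle_on_random_block(rng):
    r, blockld = random_ld_instance(rng, p=20, n_blocks=1)
    R = blockld.matrices[0]
    for s in (0.2, 0.9):
        for lam in (0.05, 0.01):
            beta = block_coordinate_descent(r, R, s, lam, config=TIGHT)
            R_s = (1 - s) * R + s * np.eye(20)
            np.testing.assert_allclose(beta, oracle_lasso(r, R_s, lam), atol=1e-6)


def test_cd_warns_on_nonconvergence(rng):
    r, blockld = random_ld_instance(rng, p=10, n_blocks=1)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        block_coordinate_descent(
            r, blockld.matrices[0], 0.2, 0.001,
            config=LassosumConfig(max_iter=1, tol=1e-14),
        )


# --- LD computation ---------------------------------------------------------


def test_compute_block_ld_structure(rng):
    dosages = rng.integers(0, 3, size=(50, 4)).astype(float)
    dosages[:, 1] = dosages[:, 0]  # perfect correlation
    dosages[:, 3] = 1.0  # constant
    panel = make_panel(dosages, spacing=10)
    blocks = LDBlocks(
        intervals=__import__("pandas").DataFrame(
            {"chrom": ["1", "1"], "start": [0, 25], "end": [25, 100]}
        )
    )
    blockld = compute_block_ld(panel, blocks)
    R0 = blockld.matrices[0]
    assert R0.shape == (2, 2)
    assert R0[0, 1] == pytest.approx(1.0)
    R1 = blockld.matrices[1]
    np.testing.assert_allclose(np.diag(R1), 1.0)
    assert R1[0, 1] == 0.0  # constant column: correlations zeroed


def test_compute_block_ld_independent_variants_near_zero(rng):
    panel = make_panel(rng.binomial(2, 0.3, size=(10_000, 6)).astype(float), spacing=10)
    blocks = LDBlocks(
        intervals=__import__("pandas").DataFrame({"chrom": ["1"], "start": [0], "end": [100]})
    )
    R = compute_block_ld(panel, blocks).matrices[0]
    off = R[~np.eye(6, dtype=bool)]
    assert np.max(np.abs(off)) < 0.05


# --- path fitting and pseudovalidation --------------------------------------


def _identity_blockld(p):
    return BlockLD(matrices=[np.eye(p)], variant_indices=[np.arange(p)], n_variants=p)


def test_path_identity_ld_equals_soft_threshold():
    stats = make_stats([0.3, 0.1])
    stats.r = np.array([0.5, 0.3])
    cfg = LassosumConfig(s_grid=(1.0,), lambda_grid=(0.4, 0.2), tol=1e-10)
    path = fit_lassosum_path(stats, _identity_blockld(2), config=cfg)
    np.testing.assert_allclose(path.coefficients[(1.0, 0.4)], [0.1, 0.0], atol=1e-9)
    np.testing.assert_allclose(path.coefficients[(1.0, 0.2)], [0.3, 0.1], atol=1e-9)


def test_path_block_separability(rng):
    r, blockld = random_ld_instance(rng, p=12, n_blocks=2)
    stats = make_stats(r)
    stats.r = r
    cfg = LassosumConfig(s_grid=(0.5,), lambda_grid=(0.05, 0.02), tol=1e-10)
    path = fit_lassosum_path(stats, blockld, config=cfg)
    for b in range(2):
        ix = blockld.variant_indices[b]
        single = BlockLD(
            matrices=[blockld.matrices[b]],
            variant_indices=[np.arange(ix.size)],
            n_variants=ix.size,
        )
        sub = make_stats(r[ix])
        sub.r = r[ix]
        sub_path = fit_lassosum_path(sub, single, config=cfg)
        for key in path.coefficients:
            np.testing.assert_allclose(
                path.coefficients[key][ix], sub_path.coefficients[key], atol=1e-10
            )


def test_path_nonzero_count_monotone_in_lambda_identity_ld(rng):
    p = 30
    r = 0.3 * rng.standard_normal(p)
    stats = make_stats(r)
    stats.r = r
    cfg = LassosumConfig(s_grid=(1.0,), lambda_grid=tuple(np.geomspace(0.5, 0.001, 12)))
    path = fit_lassosum_path(stats, _identity_blockld(p), config=cfg)
    counts = [np.count_nonzero(path.coefficients[(1.0, l)]) for l in cfg.lambda_grid]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_pseudovalidation_selects_higher_projected_correlation():
    blockld = _identity_blockld(2)
    from tlprs.lassosum import EffectPath

    path = EffectPath(
        coefficients={(1.0, 0.4): np.array([0.9, 0.0]), (1.0, 0.2): np.array([0.0, 0.1])}
    )
    stats = make_stats([0.1, 0.1])
    stats.r = np.array([0.9, 0.1])
    pseudovalidate(path, stats, blockld)
    assert path.pseudoval_score[(1.0, 0.4)] == pytest.approx(0.9)
    assert path.pseudoval_score[(1.0, 0.2)] == pytest.approx(0.1)
    assert path.selected == (1.0, 0.4)


def test_pseudovalidation_scale_invariance_and_single_candidate(rng):
    r, blockld = random_ld_instance(rng, p=8, n_blocks=1)
    from tlprs.lassosum import EffectPath

    beta = rng.standard_normal(8)
    path1 = EffectPath(coefficients={(0.5, 0.1): beta})
    path2 = EffectPath(coefficients={(0.5, 0.1): 7.3 * beta})
    stats = make_stats(r)
    stats.r = r
    pseudovalidate(path1, stats, blockld)
    pseudovalidate(path2, stats, blockld)
    assert path1.pseudoval_score[(0.5, 0.1)] == pytest.approx(
        path2.pseudoval_score[(0.5, 0.1)]
    )
    assert path1.selected == (0.5, 0.1)


def test_pseudovalidation_all_zero_raises_unless_allowed():
    blockld = _identity_blockld(2)
    from tlprs.lassosum import EffectPath

    stats = make_stats([0.0, 0.0])
    stats.r = np.array([0.1, 0.1])
    path = EffectPath(coefficients={(1.0, 0.5): np.zeros(2), (1.0, 0.3): np.zeros(2)})
    with pytest.raises(AllZeroPathError):
        pseudovalidate(path, stats, blockld)
    pseudovalidate(path, stats, blockld, allow_all_zero=True)
    assert path.selected == (1.0, 0.5)  # largest penalty wins


# --- scoring ----------------------------------------------------------------


def test_score_prs_zero_and_single_variant(tiny_panel):
    assert np.all(score_prs(tiny_panel, np.zeros(3)) == 0)
    Z = tiny_panel.standardized()
    np.testing.assert_allclose(score_prs(tiny_panel, [0, 1, 0]), Z[:, 1])


def test_score_prs_hand_computed():
    panel = make_panel([[0, 2], [1, 1], [2, 0]])
    # columns standardize to (-sqrt(3/2), 0, sqrt(3/2)) and its negation
    expect = np.array([-np.sqrt(1.5) * 2, 0.0, np.sqrt(1.5) * 2])
    np.testing.assert_allclose(score_prs(panel, [1, -1]), expect)


def test_score_prs_rejects_variant_order_mismatch(tiny_panel):
    with pytest.raises(ValueError, match="mismatch"):
        score_prs(tiny_panel, np.zeros(3), variants=["snp1", "snp0", "snp2"])


def test_select_by_validation_prefers_predictive_candidate(rng):
    panel = make_panel(rng.binomial(2, 0.4, size=(60, 3)).astype(float))
    Z = panel.standardized()
    y = Z[:, 0] + 0.1 * rng.standard_normal(60)
    from tlprs.lassosum import EffectPath

    good = np.array([1.0, 0.0, 0.0])
    bad = np.array([0.0, 1.0, 0.0])
    path = EffectPath(coefficients={(1.0, 0.1): bad, (1.0, 0.05): good})
    select_by_validation(path, panel, y, folds=5)
    assert path.selected == (1.0, 0.05)
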