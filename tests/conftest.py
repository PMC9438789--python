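import numpy as np
import pandas as pd
import pytest

from tlprs.genio import GenotypePanel, LDBlocks, SummaryStats


def make_variants(p, chrom="1", spacing=1000, prefix="snp", a1="A", a2="C"):
    idx = np.arange(p)
    return pd.DataFrame(
        {
            "id": [f"{prefix}{j}" for j in idx],
            "chrom": chrom,
            "pos": (idx + 1) * spacing,
            "a1": a1,
            "a2": a2,
        }
    )


def make_panel(dosages, phenotype=None, **variant_kwargs):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return GenotypePanel(
        dosages=dosages,
        variants=make_variants(p, **variant_kwargs),
        sample_ids=pd.DataFrame(
            {"fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)]}
        ),
        phenotype=phenotype,
    )


def make_stats(beta, se=None, pval=None, n=1000, **variant_kwargs):
    beta = np.asarray(beta, dtype=float)
    p = beta.size
    se = np.full(p, 0.1) if se is None else np.asarray(se, dtype=float)
    tstat = beta / se
    if pval is None:
        from scipy import stats as sps

        pval = 2 * sps.norm.sf(np.abs(tstat))
        pval = np.clip(pval, 1e-300, 1.0)
    return SummaryStats(
        variants=make_variants(p, **variant_kwargs),
        beta=beta,
        se=se,
        pval=np.asarray(pval, dtype=float),
        n=np.full(p, n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def tiny_panel():
    # 4 samples x 3 variants, all dosage levels represented
    return make_panel([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]])


def random_ld_instance(rng, p, n_blocks, n_ref=200):
    """Random correlations r and blockwise LD from simulated reference data."""
    sizes = np.array_split(np.arange(p), n_blocks)
    from tlprs.lassosum import BlockLD

    matrices, indices = [], []
    for ix in sizes:
        if ix.size == 0:
            continue
        G = rng.standard_normal((n_ref, ix.size))
        G += 0.5 * rng.standard_normal((n_ref, 1))  # induce correlation
        Z = (G - G.mean(0)) / G.std(0)
        R = Z.T @ Z / n_ref
        np.fill_diagonal(R, 1.0)
        matrices.append((R + R.T) / 2)
        indices.append(ix)
    r = np.clip(0.15 * rng.standard_normal(p), -0.9, 0.9)
    return r, BlockLD(matrices=matrices, variant_indices=indices, n_variants=p)
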