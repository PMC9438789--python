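"""I/O round trips, harmonization semantics and QC filters."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlprs.genio import (
    FormatError,
    LDBlocks,
    harmonize_variants,
    hwe_exact_test,
    qc_filter,
    read_ld_blocks,
    read_plink,
    read_sumstats,
    write_plink,
)

from conftest import make_panel, make_stats, make_variants


# --- PLINK binary -----------------------------------------------------------


def test_plink_round_trip_exact(tmp_path, rng):
    dosages = rng.integers(0, 3, size=(7, 5)).astype(float)
    dosages[2, 1] = np.nan  # one missing genotype
    panel = make_panel(dosages)
    write_plink(panel, str(tmp_path / "toy"))
    back = read_plink(str(tmp_path / "toy"))
    np.testing.assert_array_equal(
        np.isnan(back.dosages), np.isnan(panel.dosages)
    )
    np.testing.assert_array_equal(
        np.nan_to_num(back.dosages), np.nan_to_num(panel.dosages)
    )
    assert list(back.variants["id"]) == list(panel.variants["id"])
    assert list(back.sample_ids["iid"]) == list(panel.sample_ids["iid"])


def test_plink_missing_genotype_is_flagged_not_zero(tmp_path):
    panel = make_panel([[0.0, np.nan], [1, 2], [2, 0]])
    write_plink(panel, str(tmp_path / "m"))
    back = read_plink(str(tmp_path / "m"))
    assert math.isnan(back.dosages[0, 1])
    assert back.dosages[0, 0] == 0.0


def test_plink_rejects_sample_major_and_bad_magic(tmp_path):
    panel = make_panel([[0, 1], [1, 2], [2, 0]])
    write_plink(panel, str(tmp_path / "x"))
    bed = (tmp_path / "x.bed").read_bytes()
    (tmp_path / "x.bed").write_bytes(bed[:2] + b"\x00" + bed[3:])
    with pytest.raises(FormatError, match="sample-major"):
        read_plink(str(tmp_path / "x"))
    (tmp_path / "x.bed").write_bytes(b"\x00\x00" + bed[2:])
    with pytest.raises(FormatError, match="magic"):
        read_plink(str(tmp_path / "x"))


# --- summary statistics -----------------------------------------------------


def _write_sumstats_file(path, rows, header="id\tchrom\tpos\ta1\ta2\tbeta\tse\tn"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def test_read_sumstats_fills_tstat_and_preserves_order(tmp_path):
    rows = [f"rs{i}\t1\t{100 * (i + 1)}\tA\tG\t{0.1 * (i + 1):.2f}\t0.05\t500" for i in range(5)]
    f = tmp_path / "ss.tsv"
    _write_sumstats_file(f, rows)
    stats = read_sumstats(f)
    assert list(stats.variants["id"]) == [f"rs{i}" for i in range(5)]
    np.testing.assert_allclose(stats.tstat, stats.beta / stats.se)
    assert stats.tstat[0] == pytest.approx(0.1 / 0.05)


def test_read_sumstats_drops_nonpositive_se(tmp_path, caplog):
    rows = [
        "rs0\t1\t100\tA\tG\t0.1\t0.05\t500",
        "rs1\t1\t200\tA\tG\t0.2\t0.0\t500",
    ]
    f = tmp_path / "ss.tsv"
    _write_sumstats_file(f, rows)
    stats = read_sumstats(f)
    assert stats.n_variants == 1
    assert list(stats.variants["id"]) == ["rs0"]


def test_read_sumstats_requires_columns_and_n(tmp_path):
    f = tmp_path / "bad.tsv"
    f.write_text("id\tchrom\tpos\ta1\tbeta\n" "rs0\t1\t100\tA\t0.1\n")
    with pytest.raises(KeyError):
        read_sumstats(f)
    f2 = tmp_path / "non.tsv"
    f2.write_text("id\tchrom\tpos\ta1\ta2\tbeta\tse\n" "rs0\t1\t100\tA\tG\t0.1\t0.05\n")
    with pytest.raises(KeyError, match="sample-size"):
        read_sumstats(f2)
    stats = read_sumstats(f2, n_default=750)
    assert stats.n[0] == 750


# --- LD blocks --------------------------------------------------------------


def test_ld_blocks_reading_and_overlap_detection(tmp_path):
    f = tmp_path / "blocks.bed"
    f.write_text("1\t0\t100\n1\t100\t250\n2\t0\t50\n")
    blocks = read_ld_blocks(f)
    assert blocks.n_blocks == 3
    f.write_text("1\t0\t100\n1\t50\t150\n")
    with pytest.raises(ValueError, match="overlap"):
        read_ld_blocks(f)


def test_ld_block_boundary_convention():
    # 1-based position p belongs to [start, end) iff start < p <= end
    blocks = LDBlocks(pd.DataFrame({"chrom": ["1", "1"], "start": [0, 100], "end": [100, 200]}))
    variants = make_variants(1).assign(pos=[100])
    assert blocks.assign(variants)[0] == 0
    variants = make_variants(1).assign(pos=[101])
    assert blocks.assign(variants)[0] == 1


# --- harmonization ----------------------------------------------------------


def _two_stats_with_swap():
    ref = make_stats([0.2, 0.1, -0.3], a1="A", a2="G")
    other = make_stats([-0.2, 0.1, -0.3], a1="A", a2="G")
    other.variants.loc[0, ["a1", "a2"]] = ["G", "A"]
    other.beta[0] = -0.2  # same effect, opposite orientation
    return ref, other


def test_harmonize_sign_flips_swapped_alleles():
    ref, other = _two_stats_with_swap()
    (ha, hb), _ = harmonize_variants([ref, other], [])
    np.testing.assert_allclose(hb.beta, ha.beta)
    assert list(hb.variants["a1"]) == list(ha.variants["a1"])


def test_harmonize_drops_palindromic_variants():
    ref = make_stats([0.2, 0.1], a1="A", a2="G")
    ref.variants.loc[1, ["a1", "a2"]] = ["A", "T"]  # palindromic
    other = make_stats([0.2, 0.1], a1="A", a2="G")
    other.variants.loc[1, ["a1", "a2"]] = ["A", "T"]
    (ha, hb), _ = harmonize_variants([ref, other], [])
    assert list(ha.variants["id"]) == ["snp0"]


def test_harmonize_strand_flip_recognized():
    ref = make_stats([0.2], a1="A", a2="G")
    other = make_stats([0.2], a1="T", a2="C")  # opposite strand, same orientation
    (ha, hb), _ = harmonize_variants([ref, other], [])
    assert hb.beta[0] == pytest.approx(0.2)


def test_harmonize_is_idempotent_and_identity_on_aligned_inputs(rng):
    stats = make_stats(rng.normal(size=6), a1="A", a2="G")
    panel = make_panel(rng.integers(0, 3, size=(5, 6)), a1="A", a2="G")
    (s1,), (p1,) = harmonize_variants([stats], [panel])
    np.testing.assert_allclose(s1.beta, stats.beta)
    np.testing.assert_allclose(p1.dosages, panel.dosages)
    (s2,), (p2,) = harmonize_variants([s1], [p1])
    np.testing.assert_allclose(s2.beta, s1.beta)
    np.testing.assert_allclose(p2.dosages, p1.dosages)


@given(st.lists(st.floats(-1, 1), min_size=3, max_size=3))
@settings(deadline=None, max_examples=25)
def test_sign_flip_involution(betas):
    stats = make_stats(np.asarray(betas), a1="A", a2="G")
    mask = np.array([True, False, True])
    back = stats.flip_alleles(mask).flip_alleles(mask)
    np.testing.assert_allclose(back.beta, stats.beta)
    np.testing.assert_allclose(back.tstat, stats.tstat)
    assert list(back.variants["a1"]) == list(stats.variants["a1"])


# --- Hardy-Weinberg ---------------------------------------------------------


def _hwe_oracle(n_hom1, n_het, n_hom2):
    """Exact-fraction enumeration over heterozygote counts."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    probs = {}
    for k in range(rare % 2, rare + 1, 2):
        homr = (rare - k) // 2
        homc = n - k - homr
        probs[k] = (
            Fraction(2) ** k
            * Fraction(math.factorial(n), math.factorial(homr))
            / math.factorial(k)
            / math.factorial(homc)
        )
    total = sum(probs.values())
    obs = probs[n_het]
    return float(sum(v for v in probs.values() if v <= obs) / total)


def test_hwe_examples():
    assert hwe_exact_test((0, 0, 50)) == 1.0
    assert hwe_exact_test((25, 50, 25)) == pytest.approx(1.0)
    assert hwe_exact_test((50, 0, 50)) < 1e-5
    with pytest.raises(ValueError):
        hwe_exact_test((-1, 2, 3))


def test_hwe_matches_enumeration_oracle_small_totals():
    for total in (2, 5, 11, 20, 50):
        for n_het in range(0, total + 1, max(1, total // 5)):
            for n_hom1 in range(0, total - n_het + 1, max(1, total // 4)):
                n_hom2 = total - n_het - n_hom1
                got = hwe_exact_test((n_hom1, n_het, n_hom2))
                want = _hwe_oracle(n_hom1, n_het, n_hom2)
                assert got == pytest.approx(want, abs=1e-12), (n_hom1, n_het, n_hom2)


# --- QC ---------------------------------------------------------------------


def test_qc_filter_removes_rare_and_out_of_hwe_variants(rng):
    n = 200
    common = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
    rare = np.zeros((n, 1))
    rare[0, 0] = 1.0  # MAF = 0.0025
    weird = np.concatenate([np.full(n // 2, 0.0), np.full(n // 2, 2.0)])[:, None]
    panel = make_panel(np.hstack([common, rare, weird]))
    kept = qc_filter(panel)
    assert list(kept.variants["id"]) == ["snp0"]


def test_qc_filter_keeps_good_variants(rng):
    maf = 0.3
    dosages = rng.binomial(2, maf, size=(500, 10)).astype(float)
    panel = make_panel(dosages)
    kept = qc_filter(panel)
    assert kept.n_variants == 10
    with pytest.raises(ValueError):
        qc_filter(make_panel(np.zeros((50, 2))))
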