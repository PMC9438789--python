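"""Genotype/summary-statistics I/O, variant harmonization and QC.

Reads and writes the plain-text and PLINK 1 binary formats the PRS
pipeline touches, aligns variants across populations (allele swaps,
strand flips, palindromic exclusion) and applies the standard per-variant
QC filters (minor allele frequency, Hardy-Weinberg equilibrium).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(ValueError):
    """Companion files disagree with each other (e.g. .bed vs .fam/.bim)."""


@dataclass(frozen=True)
class VariantRecord:
    """Identity of one variant: id, position and the two alleles.

    ``a1`` is the effect allele (the allele whose dosage is counted and to
    which effect sizes refer), ``a2`` the other allele.
    """

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("variant id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.a1 == self.a2:
            raise ValueError(f"alleles must differ, got {self.a1}/{self.a2}")


def _as_variant_frame(variants) -> pd.DataFrame:
    """Normalize a variant table (DataFrame or iterable of records)."""
    if isinstance(variants, pd.DataFrame):
        missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        df = variants[VARIANT_COLUMNS].reset_index(drop=True).copy()
    else:
        df = pd.DataFrame(
            [(v.id, v.chrom, v.pos, v.a1, v.a2) for v in variants],
            columns=VARIANT_COLUMNS,
        )
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    return df


@dataclass
class SummaryStats:
    """Per-variant GWAS association results for one population.

    All arrays are aligned with ``variants`` (row i describes variant i).
    ``beta``/``se`` are on the standardized-genotype scale; ``r`` is the
    SNP-wise correlation derived from the t-statistic, r = t/sqrt(n-1+t^2).
    """

    variants: pd.DataFrame
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    n: np.ndarray
    tstat: np.ndarray | None = None
    r: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variants = _as_variant_frame(self.variants)
        p = len(self.variants)
        for name in ("beta", "se", "pval", "n", "tstat", "r"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=np.int64 if name == "n" else float)
            if arr.shape != (p,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({p},)")
            setattr(self, name, arr)
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")
        if self.tstat is None:
            self.tstat = self.beta / self.se

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, idx: np.ndarray) -> "SummaryStats":
        """Row-subset (and/or reorder) by integer index array."""
        return SummaryStats(
            variants=self.variants.iloc[idx],
            beta=self.beta[idx],
            se=self.se[idx],
            pval=self.pval[idx],
            n=self.n[idx],
            tstat=self.tstat[idx],
            r=None if self.r is None else self.r[idx],
        )

    def flip_alleles(self, mask: np.ndarray) -> "SummaryStats":
        """Swap a1/a2 for masked variants, negating beta, tstat and r."""
        sign = np.where(mask, -1.0, 1.0)
        variants = self.variants.copy()
        a1 = variants.loc[mask, "a1"].copy()
        variants.loc[mask, "a1"] = variants.loc[mask, "a2"]
        variants.loc[mask, "a2"] = a1
        return SummaryStats(
            variants=variants,
            beta=self.beta * sign,
            se=self.se,
            pval=self.pval,
            n=self.n,
            tstat=self.tstat * sign,
            r=None if self.r is None else self.r * sign,
        )


@dataclass
class GenotypePanel:
    """n_samples x n_variants dosage matrix with variant/sample metadata.

    Dosages count copies of each variant's effect allele (a1) and are in
    {0, 1, 2}; missing genotypes are NaN.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: pd.DataFrame  # columns fid, iid
    phenotype: np.ndarray | None = None
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = _as_variant_frame(self.variants)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, p = self.dosages.shape
        if p != len(self.variants):
            raise ConsistencyError(
                f"dosage matrix has {p} columns but {len(self.variants)} variants"
            )
        if not isinstance(self.sample_ids, pd.DataFrame):
            self.sample_ids = pd.DataFrame(
                list(self.sample_ids), columns=["fid", "iid"]
            )
        self.sample_ids = self.sample_ids.reset_index(drop=True)
        if len(self.sample_ids) != n:
            raise ConsistencyError(
                f"dosage matrix has {n} rows but {len(self.sample_ids)} samples"
            )
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if self.phenotype.shape != (n,):
                raise ValueError("phenotype length must equal sample count")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the effect allele (a1), ignoring missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def standardized(self) -> np.ndarray:
        """Mean-imputed, zero-mean, unit-variance dosage matrix.

        Missing entries are replaced by the variant mean (hence 0 after
        centering); constant variants map to all-zero columns. The result
        is cached; do not mutate ``dosages`` in place (build a new panel
        instead).
        """
        cached = getattr(self, "_std_cache", None)
        if cached is not None:
            return cached
        X = self.dosages.copy()
        mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        idx = np.where(np.isnan(X))
        X[idx] = mean[idx[1]]
        X -= mean
        sd = X.std(axis=0, ddof=0)
        nonconst = sd > 0
        X[:, nonconst] /= sd[nonconst]
        X[:, ~nonconst] = 0.0
        self._std_cache = X
        return X

    def subset_variants(self, idx: np.ndarray) -> "GenotypePanel":
        return replace(
            self,
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx],
        )

    def flip_alleles(self, mask: np.ndarray) -> "GenotypePanel":
        """Swap a1/a2 for masked variants: dosage -> 2 - dosage (NaN kept)."""
        dos = self.dosages.copy()
        dos[:, mask] = 2.0 - dos[:, mask]
        variants = self.variants.copy()
        a1 = variants.loc[mask, "a1"].copy()
        variants.loc[mask, "a1"] = variants.loc[mask, "a2"]
        variants.loc[mask, "a2"] = a1
        return replace(self, dosages=dos, variants=variants)


@dataclass
class LDBlocks:
    """Ordered, non-overlapping genomic intervals partitioning the variants.

    Intervals are BED-style 0-based half-open [start, end); a variant at
    1-based position p belongs to [start, end) iff start < p <= end.
    """

    intervals: pd.DataFrame  # columns chrom, start, end
    assignment: np.ndarray | None = None  # variant index -> block index

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError(f"empty or inverted interval on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping LD blocks on chromosome {chrom}")
        self.intervals = df

    @property
    def n_blocks(self) -> int:
        return len(self.intervals)

    def assign(self, variants: pd.DataFrame) -> np.ndarray:
        """Map each variant to its block index; unassigned variants -> -1."""
        variants = _as_variant_frame(variants)
        out = np.full(len(variants), -1, dtype=np.int64)
        for b, row in self.intervals.iterrows():
            # 1-based position p is inside [start, end) iff start < p <= end
            mask = (
                (variants["chrom"] == row["chrom"])
                & (variants["pos"] > row["start"])
                & (variants["pos"] <= row["end"])
            ).to_numpy()
            out[mask] = b
        self.assignment = out
        return out


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

_PLINK_MAGIC = b"\x6c\x1b"
# 2-bit genotype codes (variant-major): 00=hom a1, 01=missing, 10=het, 11=hom a2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

_BYTE_TABLE = np.empty((256, 4))
for _b in range(256):
    for _k in range(4):
        _BYTE_TABLE[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


def read_plink(prefix_or_bed, bim_path=None, fam_path=None) -> GenotypePanel:
    """Read a PLINK 1 binary fileset (.bed/.bim/.fam) into a GenotypePanel.

    Accepts either a common prefix or the three explicit paths. Only the
    variant-major layout (third magic byte 0x01) is supported. Dosages
    count the .bim A1 allele; missing genotypes become NaN.
    """
    if bim_path is None and fam_path is None:
        prefix = str(prefix_or_bed)
        if prefix.endswith(".bed"):
            prefix = prefix[:-4]
        bed_path = prefix + ".bed"
        bim_path = prefix + ".bim"
        fam_path = prefix + ".fam"
    else:
        bed_path = str(prefix_or_bed)

    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n, p = len(fam), len(bim)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _PLINK_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes, not a PLINK 1 .bed file")
    if raw[2:3] != b"\x01":
        raise FormatError(
            f"{bed_path}: sample-major .bed layout is not supported "
            "(only variant-major, third byte 0x01)"
        )
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * p:
        raise ConsistencyError(
            f"{bed_path}: {body.size} data bytes, expected "
            f"{bytes_per_variant * p} for {n} samples x {p} variants"
        )
    decoded = _BYTE_TABLE[body.reshape(p, bytes_per_variant)]
    dosages = decoded.reshape(p, bytes_per_variant * 4)[:, :n].T

    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    phenotype = fam["phenotype"].to_numpy(dtype=float)
    if np.all(phenotype == -9):
        phenotype = None
    return GenotypePanel(
        dosages=dosages,
        variants=variants,
        sample_ids=fam[["fid", "iid"]],
        phenotype=phenotype,
    )


def write_plink(panel: GenotypePanel, prefix: str) -> None:
    """Write a GenotypePanel as a PLINK 1 variant-major fileset."""
    prefix = str(prefix)
    n, p = panel.dosages.shape

    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids["fid"],
            "iid": panel.sample_ids["iid"],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": panel.phenotype if panel.phenotype is not None else -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"],
            "id": panel.variants["id"],
            "cm": 0,
            "pos": panel.variants["pos"],
            "a1": panel.variants["a1"],
            "a2": panel.variants["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    # dosage -> 2-bit code: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
    codes = np.where(
        np.isnan(panel.dosages),
        1,
        np.select(
            [panel.dosages == 2, panel.dosages == 1, panel.dosages == 0],
            [0, 2, 3],
            default=1,
        ),
    ).astype(np.uint8)
    bytes_per_variant = (n + 3) // 4
    padded = np.ones((p, bytes_per_variant * 4), dtype=np.uint8) * 3  # pad hom-a2
    padded[:, :n] = codes.T
    packed = np.zeros((p, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC + b"\x01")
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Summary statistics and LD blocks
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "id": "id",
    "chrom": "chrom",
    "pos": "pos",
    "a1": "a1",
    "a2": "a2",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "tstat": "tstat",
}


def read_sumstats(
    path, column_map: dict | None = None, n_default: int | None = None
) -> SummaryStats:
    """Read a GWAS summary-statistics TSV.

    ``column_map`` maps canonical names (id, chrom, pos, a1, a2, beta, se,
    pval, n, tstat) to the file's column names. At least one of
    (beta, se), (tstat) or (pval + signed beta) must be present; a single
    study-wide sample size may be supplied via ``n_default`` when the file
    has no per-variant n column. Rows with non-positive standard errors
    are dropped (count logged).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["id"]: str, cmap["chrom"]: str})

    for key in ("id", "chrom", "pos", "a1", "a2"):
        if cmap[key] not in df.columns:
            raise KeyError(f"summary-statistics file lacks required column '{cmap[key]}'")

    def col(key):
        name = cmap[key]
        return df[name].to_numpy(dtype=float) if name in df.columns else None

    beta, se, pval, tstat = col("beta"), col("se"), col("pval"), col("tstat")
    if cmap["n"] in df.columns:
        n = df[cmap["n"]].to_numpy(dtype=np.int64)
    elif n_default is not None:
        n = np.full(len(df), int(n_default), dtype=np.int64)
    else:
        raise KeyError(
            "summary-statistics file has no sample-size column and no "
            "study-wide n was supplied"
        )

    if se is not None:
        bad = ~(se > 0)
        if bad.any():
            logger.warning("dropping %d rows with non-positive SE", int(bad.sum()))
            keep = ~bad
            df = df.loc[keep]
            beta = beta[keep]
            se = se[keep]
            n = n[keep]
            pval = None if pval is None else pval[keep]
            tstat = None if tstat is None else tstat[keep]

    from scipy import stats as sps

    if beta is not None and se is not None:
        if tstat is None:
            tstat = beta / se
    elif tstat is not None:
        # reconstruct beta/se on the standardized scale from t and n
        se = 1.0 / np.sqrt(np.maximum(n - 2, 1) + tstat**2)
        beta = tstat * se
    elif pval is not None and beta is not None:
        tstat = np.sign(beta) * sps.norm.isf(np.clip(pval, 1e-300, 1.0) / 2)
        se = np.abs(beta / np.where(tstat == 0, np.nan, tstat))
        se = np.where(np.isnan(se), 1.0, se)
    else:
        raise KeyError(
            "need (beta, se), tstat, or (pval + signed beta) columns in "
            "summary statistics"
        )
    if pval is None:
        dof = np.maximum(n - 2, 1)
        pval = 2 * sps.t.sf(np.abs(tstat), dof)
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)

    variants = pd.DataFrame(
        {
            "id": df[cmap["id"]].astype(str),
            "chrom": df[cmap["chrom"]].astype(str),
            "pos": df[cmap["pos"]].astype(np.int64),
            "a1": df[cmap["a1"]].astype(str),
            "a2": df[cmap["a2"]].astype(str),
        }
    )
    return SummaryStats(
        variants=variants, beta=beta, se=se, pval=pval, n=n, tstat=tstat
    )


def write_sumstats(stats: SummaryStats, path) -> None:
    out = stats.variants.copy()
    out["beta"] = stats.beta
    out["se"] = stats.se
    out["tstat"] = stats.tstat
    out["pval"] = stats.pval
    out["n"] = stats.n
    out.to_csv(path, sep="\t", index=False)


def read_ld_blocks(path) -> LDBlocks:
    """Read LD-block definitions from a 3-column BED file (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    return LDBlocks(intervals=df)


def write_ld_blocks(blocks: LDBlocks, path) -> None:
    blocks.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def _match_alleles(ref_a1, ref_a2, a1, a2):
    """Classify allele pair vs the reference: 'same', 'flip' or None."""
    a1, a2 = a1.upper(), a2.upper()
    ref_a1, ref_a2 = ref_a1.upper(), ref_a2.upper()
    if (a1, a2) == (ref_a1, ref_a2):
        return "same"
    if (a1, a2) == (ref_a2, ref_a1):
        return "flip"
    c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if (c1, c2) == (ref_a1, ref_a2):
        return "same"  # opposite strand, same orientation
    if (c1, c2) == (ref_a2, ref_a1):
        return "flip"
    return None


def harmonize_variants(stats_list, panels):
    """Align one or more SummaryStats and GenotypePanels on shared variants.

    The first summary-statistics input (or first panel if no stats) defines
    the reference allele orientation and the canonical variant order.
    Variants with swapped a1/a2 (on either strand) are sign-flipped;
    strand-ambiguous palindromic variants (A/T, C/G) and variants with
    irreconcilable alleles are dropped. Returns ``(stats_out, panels_out)``
    lists whose variant tables are identical across all outputs.
    """
    stats_list = list(stats_list)
    panels = list(panels)
    inputs = [(s.variants, "stats") for s in stats_list] + [
        (p.variants, "panel") for p in panels
    ]
    if not inputs:
        raise ValueError("harmonize_variants needs at least one input")

    ref = inputs[0][0]
    palin = ref.apply(lambda row: _is_palindromic(row["a1"], row["a2"]), axis=1)
    n_palin = int(palin.sum())
    keep_ids = set(ref.loc[~palin.to_numpy(), "id"])

    # intersect ids, dropping irreconcilable-allele variants as we go
    actions = []  # per input: dict id -> 'same' | 'flip'
    for variants, _kind in inputs:
        ref_idx = ref.set_index("id")
        act = {}
        for _, row in variants.iterrows():
            vid = row["id"]
            if vid not in keep_ids or vid not in ref_idx.index:
                continue
            rrow = ref_idx.loc[vid]
            m = _match_alleles(rrow["a1"], rrow["a2"], row["a1"], row["a2"])
            if m is None:
                keep_ids.discard(vid)
            else:
                act[vid] = m
        actions.append(act)
        keep_ids &= set(act)

    if not keep_ids:
        raise ValueError("no shared variants after harmonization")

    order = [vid for vid in ref["id"] if vid in keep_ids]
    n_flip = 0
    outputs = []
    for (variants, _kind), act, obj in zip(
        inputs, actions, stats_list + panels
    ):
        pos_of = {vid: i for i, vid in enumerate(variants["id"])}
        idx = np.array([pos_of[vid] for vid in order], dtype=np.int64)
        sub = obj.subset(idx) if isinstance(obj, SummaryStats) else obj.subset_variants(idx)
        flip_mask = np.array([act[vid] == "flip" for vid in order])
        n_flip += int(flip_mask.sum())
        if flip_mask.any():
            sub = sub.flip_alleles(flip_mask)
        # after strand normalization, adopt the reference allele labels
        sub.variants["a1"] = ref.set_index("id").loc[order, "a1"].to_numpy()
        sub.variants["a2"] = ref.set_index("id").loc[order, "a2"].to_numpy()
        outputs.append(sub)

    logger.info(
        "harmonized %d variants (%d palindromic dropped, %d orientation flips)",
        len(order),
        n_palin,
        n_flip,
    )
    n_stats = len(stats_list)
    return outputs[:n_stats], outputs[n_stats:]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_exact_test(genotype_counts) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa). The p-value sums the
    probabilities of all heterozygote configurations (conditional on the
    observed allele counts) that are at most as probable as the observed
    one — the standard exact test, not mid-p.
    """
    n_hom1, n_het, n_hom2 = (int(c) for c in genotype_counts)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_hom1 + n_het  # copies of allele A
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0

    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = k | allele counts) up to a common constant
    homr = (rare - hets) // 2
    homc = (n - hets - homr)
    logp = (
        hets * np.log(2.0)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_het)]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def qc_filter(
    panel: GenotypePanel, maf_min: float = 0.01, hwe_p_min: float = 1e-5
) -> GenotypePanel:
    """Drop variants failing MAF or Hardy-Weinberg filters.

    A variant is removed when its minor allele frequency is <= ``maf_min``
    or its HWE exact-test p-value is < ``hwe_p_min``.
    """
    freqs = panel.allele_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    keep = maf > maf_min
    for j in np.flatnonzero(keep):
        col = panel.dosages[:, j]
        col = col[~np.isnan(col)]
        counts = (int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        if hwe_exact_test(counts) < hwe_p_min:
            keep[j] = False
    if not keep.any():
        raise ValueError("QC filter removed every variant")
    removed = int((~keep).sum())
    if removed:
        logger.info("QC removed %d of %d variants", removed, panel.n_variants)
    return panel.subset_variants(np.flatnonzero(keep))
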