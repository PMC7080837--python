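"""Genotype matrices, sample metadata, and quality filtering.

Reads biallelic SNP genotypes (with per-genotype depth and quality) from VCF
and applies the two filter chains used throughout the package:

* the *phylogenetic-grade* chain — genotype masking by depth/quality, then
  removal of sites that are monomorphic after masking, too incomplete, or
  excessively heterozygous;
* the *popgen-grade* chain — genotype masking, then removal of sites with
  high mean depth, low minor-allele frequency, or significant heterozygote
  excess, optionally followed by LD pruning within physical windows.

The fixed filter order is mask -> site filters -> prune; every stage logs
the surviving site count and the convenience pipelines return a JSON-able
report of those counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger("hybridscan")

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "mask_genotypes",
    "filter_sites_phylo",
    "filter_sites_popgen",
    "ld_prune",
    "het_excess_pvalue",
    "apply_phylo_pipeline",
    "apply_popgen_pipeline",
]

MISSING = -1

METADATA_COLUMNS = ["sample_id", "species", "population", "site",
                    "mito_species", "core_group", "hybrid_status"]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x biallelic sites, genotype = alternate-allele count.

    gt is int8 with -1 for missing; dp (read depth) and gq (phred genotype
    quality) share the (n_sites, n_samples) shape.  Positions are 1-based as
    in VCF and strictly increasing within a chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_samples = self.gt.shape
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == n_sites):
            raise ValueError("site annotation length mismatch")
        if len(self.samples) != n_samples:
            raise ValueError("sample count mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return replace(self, chrom=self.chrom[index], pos=self.pos[index],
                       ref=self.ref[index], alt=self.alt[index],
                       gt=self.gt[index], dp=self.dp[index], gq=self.gq[index])

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[s] for s in ids])
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def alt_frequency(self, sample_index=None) -> np.ndarray:
        """Per-site alternate-allele frequency over called genotypes
        (NaN where no genotype is called)."""
        g = self.gt if sample_index is None else self.gt[:, sample_index]
        called = g >= 0
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def species_frequencies(self, meta: pd.DataFrame, species: list[str] | None = None,
                            core_only: bool = False) -> pd.DataFrame:
        """Alternate-allele frequency table, one column per species."""
        if species is None:
            species = sorted(meta["species"].unique())
        out = {}
        for sp in species:
            rows = meta[meta["species"] == sp]
            if core_only:
                rows = rows[rows["core_group"].astype(bool)]
            out[sp] = self.alt_frequency(self.sample_indices(rows["sample_id"]))
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# VCF and metadata I/O
# ---------------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs (GT, DP, GQ) from a VCF via cyvcf2.

    Non-biallelic or non-SNP records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, gts, dps, gqs = [], [], [], [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        g = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = MISSING
        gts.append(g)
        dp = v.format("DP")
        gq = v.format("GQ")
        dps.append(np.zeros(len(samples), dtype=np.int32) if dp is None
                   else np.maximum(dp.reshape(-1).astype(np.int32), 0))
        gqs.append(np.zeros(len(samples), dtype=np.int32) if gq is None
                   else np.maximum(gq.reshape(-1).astype(np.int32), 0))
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    return GenotypeMatrix(np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64),
                          np.asarray(ref, dtype=object), np.asarray(alt, dtype=object),
                          samples, np.asarray(gts, dtype=np.int8),
                          np.asarray(dps, dtype=np.int32), np.asarray(gqs, dtype=np.int32))


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCF with GT:DP:GQ FORMAT fields."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for c in dict.fromkeys(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            fields = [str(gm.chrom[i]), str(gm.pos[i]), ".", str(gm.ref[i]), str(gm.alt[i]),
                      ".", "PASS", ".", "GT:DP:GQ"]
            for j in range(gm.n_samples):
                fields.append(f"{gt_str[int(gm.gt[i, j])]}:{int(gm.dp[i, j])}:{int(gm.gq[i, j])}")
            fh.write("\t".join(fields) + "\n")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id", "species") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks required columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def mask_genotypes(gm: GenotypeMatrix, min_depth: int = 5, max_depth: int | None = 50,
                   min_gq: int = 30) -> GenotypeMatrix:
    """Set genotypes to missing where depth is below ``min_depth``, above
    ``max_depth`` (strict inequalities), or genotype quality is below
    ``min_gq``.  Passing entries are unchanged."""
    if min_depth < 0 or min_gq < 0 or (max_depth is not None and max_depth <= 0):
        raise ValueError("thresholds must be positive")
    bad = (gm.dp < min_depth) | (gm.gq < min_gq)
    if max_depth is not None:
        bad |= gm.dp > max_depth
    gt = gm.gt.copy()
    gt[bad] = MISSING
    out = replace(gm, gt=gt)
    logger.info("mask_genotypes: masked %d genotypes", int(np.sum(bad & (gm.gt >= 0))))
    return out


def _het_fraction(gm: GenotypeMatrix) -> np.ndarray:
    called = (gm.gt >= 0).sum(axis=1)
    het = (gm.gt == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, het / np.maximum(called, 1), 0.0)


def _polymorphic(gm: GenotypeMatrix) -> np.ndarray:
    called = gm.gt >= 0
    alt = np.where(called, gm.gt, 0).sum(axis=1)
    n_alleles = 2 * called.sum(axis=1)
    return (alt > 0) & (alt < n_alleles)


def filter_sites_phylo(gm: GenotypeMatrix, max_missing_fraction: float = 0.3,
                       max_het: float = 0.5) -> GenotypeMatrix:
    """Drop sites monomorphic after masking, sites with a missing-genotype
    fraction >= ``max_missing_fraction``, and sites with observed
    heterozygosity > ``max_het``."""
    if not (0 <= max_missing_fraction <= 1 and 0 <= max_het <= 1):
        raise ValueError("fractions must be in [0, 1]")
    missing_frac = (gm.gt < 0).mean(axis=1)
    keep = _polymorphic(gm) & (missing_frac < max_missing_fraction) & (_het_fraction(gm) <= max_het)
    out = gm.take_sites(keep)
    logger.info("filter_sites_phylo: %d -> %d sites", gm.n_sites, out.n_sites)
    return out


def het_excess_pvalue(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """One-sided exact Hardy-Weinberg test toward heterozygote excess.

    Uses the conditional (Levene/Haldane) distribution of the heterozygote
    count given the sample size and minor-allele count; returns
    P(N_het >= observed)."""
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = 2 * n_hom_alt + n_het
    m = min(n_alt, 2 * n - n_alt)  # minor-allele count
    hs = np.arange(m % 2, m + 1, 2)  # heterozygote counts sharing the parity of m
    # log P(h) up to a constant: 2^h * n! / (n_minor_hom! h! n_major_hom!)
    logp = (hs * np.log(2.0) - gammaln((m - hs) / 2 + 1) - gammaln(hs + 1)
            - gammaln((2 * n - m - hs) / 2 + 1))
    logp -= logsumexp(logp)
    return float(np.exp(logsumexp(logp[hs >= n_het])))


def filter_sites_popgen(gm: GenotypeMatrix, max_mean_depth: float = 50.0,
                        min_maf: float = 0.02, het_excess_alpha: float = 0.05) -> GenotypeMatrix:
    """Drop sites with mean depth above ``max_mean_depth``, minor-allele
    frequency below ``min_maf``, or significant heterozygote excess."""
    if min_maf < 0 or min_maf > 0.5 or het_excess_alpha <= 0:
        raise ValueError("invalid thresholds")
    called = gm.gt >= 0
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(n_called > 0, np.where(called, gm.dp, 0).sum(axis=1)
                              / np.maximum(n_called, 1), 0.0)
    freq = gm.alt_frequency()
    maf = np.fmin(freq, 1.0 - freq)
    keep = (mean_depth <= max_mean_depth) & (maf >= min_maf)
    for i in np.nonzero(keep)[0]:
        g = gm.gt[i][called[i]]
        p = het_excess_pvalue(int(np.sum(g == 1)), int(np.sum(g == 0)), int(np.sum(g == 2)))
        if p < het_excess_alpha:
            keep[i] = False
    out = gm.take_sites(keep)
    logger.info("filter_sites_popgen: %d -> %d sites", gm.n_sites, out.n_sites)
    return out


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of alt-allele counts, pairwise-complete."""
    ok = (a >= 0) & (b >= 0)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0 if sx == 0 and sy == 0 else 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, window_bp: int = 10_000, r2_max: float = 0.8) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning per chromosome: a site is removed if
    its genotype r^2 with any *retained* site within ``window_bp`` upstream
    exceeds ``r2_max``."""
    if window_bp < 1:
        raise ValueError("window must be >= 1 bp")
    keep = np.zeros(gm.n_sites, dtype=bool)
    for c in np.unique(gm.chrom):
        idx = np.nonzero(gm.chrom == c)[0]
        retained: list[int] = []
        for i in idx:
            linked = False
            for j in reversed(retained):
                if gm.pos[i] - gm.pos[j] > window_bp:
                    break
                if _pairwise_r2(gm.gt[i], gm.gt[j]) > r2_max:
                    linked = True
                    break
            if not linked:
                retained.append(i)
                keep[i] = True
    out = gm.take_sites(keep)
    logger.info("ld_prune: %d -> %d sites", gm.n_sites, out.n_sites)
    return out


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------


def apply_phylo_pipeline(gm: GenotypeMatrix, min_depth: int = 5, max_depth: int = 50,
                         min_gq: int = 30, max_missing_fraction: float = 0.3,
                         max_het: float = 0.5) -> tuple[GenotypeMatrix, dict]:
    """Mask genotypes then apply the phylogenetic-grade site filters."""
    report = {"input_sites": gm.n_sites}
    gm = mask_genotypes(gm, min_depth, max_depth, min_gq)
    gm = filter_sites_phylo(gm, max_missing_fraction, max_het)
    report["after_site_filters"] = gm.n_sites
    return gm, report


def apply_popgen_pipeline(gm: GenotypeMatrix, min_depth: int = 5, min_gq: int = 30,
                          max_mean_depth: float = 50.0, min_maf: float = 0.02,
                          het_excess_alpha: float = 0.05, prune: bool = True,
                          window_bp: int = 10_000, r2_max: float = 0.8) -> tuple[GenotypeMatrix, dict]:
    """Mask genotypes, apply popgen-grade site filters, optionally LD-prune."""
    report = {"input_sites": gm.n_sites}
    gm = mask_genotypes(gm, min_depth, None, min_gq)
    gm = filter_sites_popgen(gm, max_mean_depth, min_maf, het_excess_alpha)
    report["after_site_filters"] = gm.n_sites
    if prune:
        gm = ld_prune(gm, window_bp, r2_max)
        report["after_ld_prune"] = gm.n_sites
    return gm, report
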