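"""Population-genetic summaries: distances, diversity, rate conversions.

Covers the uncorrected p-distance between species (from allele frequencies
at jointly called sites), Watterson's theta with per-site sample sizes,
conversion of a pairwise distance plus a divergence time into a per-site
per-generation mutation rate, and a nearest-reference mitochondrial species
assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "p_distance",
    "watterson_theta",
    "mutation_rate",
    "assign_mito_species",
]

MUTATION_RATE_CONVENTIONS = ("half-distance", "full-distance")


def _species_sample_index(gm: GenotypeMatrix, meta: pd.DataFrame, species: str,
                          exclude_hybrids: bool) -> np.ndarray:
    rows = meta[meta["species"] == species]
    if exclude_hybrids and "hybrid_status" in meta.columns:
        rows = rows[rows["hybrid_status"].isin(["pure"]) | rows["hybrid_status"].isna()]
    if rows.empty:
        raise ValueError(f"no samples for species {species!r}")
    return gm.sample_indices(rows["sample_id"])


def p_distance(gm: GenotypeMatrix, meta: pd.DataFrame, species_a: str, species_b: str,
               exclude_hybrids: bool = True) -> float:
    """Uncorrected p-distance between two species over the assayed sites.

    Per site the expected allele mismatch probability between a random
    allele from each species is p_a(1-p_b) + p_b(1-p_a); the distance is the
    mean over sites called in both species.  Individuals flagged as hybrids
    in the metadata are excluded when requested.  Note the denominator is
    the provided site set, so on a SNP-only matrix this is a distance per
    variant site, not per genomic bp.
    """
    ia = _species_sample_index(gm, meta, species_a, exclude_hybrids)
    ib = _species_sample_index(gm, meta, species_b, exclude_hybrids)
    pa = gm.alt_frequency(ia)
    pb = gm.alt_frequency(ib)
    ok = np.isfinite(pa) & np.isfinite(pb)
    if not ok.any():
        raise ValueError("no sites called in both species")
    mism = pa[ok] * (1 - pb[ok]) + pb[ok] * (1 - pa[ok])
    return float(mism.mean())


def watterson_theta(gm: GenotypeMatrix, meta: pd.DataFrame, species: str) -> float:
    """Watterson's theta per site with per-site sample sizes.

    Missing data are handled per site: a site with n_s >= 2 called
    chromosomes contributes 1/a_{n_s} if segregating within the species
    (a_n the harmonic number over n-1 terms), and every such site counts
    toward the assayed length L.
    """
    idx = _species_sample_index(gm, meta, species, exclude_hybrids=True)
    g = gm.gt[:, idx]
    called = g >= 0
    n_chrom = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    usable = n_chrom >= 2
    if not usable.any():
        raise ValueError(f"fewer than 2 called chromosomes at every site for {species!r}")
    seg = usable & (alt > 0) & (alt < n_chrom)
    harm = np.concatenate([[0.0, 0.0], np.cumsum(1.0 / np.arange(1, n_chrom.max()))])
    contrib = np.zeros(gm.n_sites)
    contrib[seg] = 1.0 / harm[n_chrom[seg]]
    return float(contrib.sum() / usable.sum())


def mutation_rate(p_dist: float, t_ma: float, g_years: float,
                  convention: str = "half-distance") -> dict:
    """Convert a pairwise distance and divergence time to a rate per site
    per generation.

    half-distance (default): r = (p/2) * g / (T * 1e6) — per-lineage
    distance accumulated over T/g generations.  full-distance:
    r = p * g / (T * 1e6).  The convention used is returned with the value.
    """
    if t_ma <= 0 or g_years <= 0:
        raise ValueError("divergence time and generation time must be positive")
    if convention not in MUTATION_RATE_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; choose from {MUTATION_RATE_CONVENTIONS}")
    gens_per_lineage = t_ma * 1e6 / g_years
    per_lineage = p_dist / 2.0 if convention == "half-distance" else p_dist
    return {"rate": per_lineage / gens_per_lineage, "convention": convention,
            "p_distance": p_dist, "t_ma": t_ma, "generation_years": g_years}


def assign_mito_species(query: str, references: dict[str, str]) -> tuple[str, float]:
    """Assign a mitochondrial sequence to the nearest reference haplotype.

    Distance is the uncorrected mismatch fraction over positions where both
    sequences have an unambiguous base.  Returns (species, distance); ties
    break to the alphabetically first species for determinism.
    """
    if not references:
        raise ValueError("no reference haplotypes")
    q = np.frombuffer(query.upper().encode(), dtype="S1")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    best: tuple[float, str] | None = None
    for sp in sorted(references):
        r = np.frombuffer(references[sp].upper().encode(), dtype="S1")
        if len(r) != len(q):
            raise ValueError(f"reference for {sp!r} has different length than query")
        ok = np.isin(q, bases) & np.isin(r, bases)
        if not ok.any():
            continue
        d = float(np.mean(q[ok] != r[ok]))
        if best is None or d < best[0]:
            best = (d, sp)
    if best is None:
        raise ValueError("no comparable positions against any reference")
    return best[1], best[0]
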