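"""Ancestry painting of putative hybrids at species-diagnostic fixed sites.

A fixed-site panel holds the sites at which two parental species' core
groups are fixed for different alleles.  A putative hybrid is "painted" by
classifying its genotype at every panel site as homozygous-maternal,
heterozygous, or homozygous-paternal (the maternal side is identified by
the hybrid's mitochondrial species).  From the painting follow the
heterozygosity H, the maternal genome fraction

    f_m,genome = (2 * N_hom_m + N_het) / (2 * called sites),

and a hybrid class: F1s are expected heterozygous at nearly all panel sites
(H near 1) while first-generation backcrosses sit near H = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger("hybridscan")

__all__ = [
    "FixedSitePanel",
    "AncestryPainting",
    "find_fixed_sites",
    "paint",
    "classify_hybrid",
    "cohort_summary",
    "paintings_to_frame",
    "plot_painting",
]


@dataclass
class FixedSitePanel:
    """Sites fixed for different alleles in species A vs species B.

    ``gt_a`` is the alternate-allele count (0 or 2) carried by species A at
    each site; species B carries 2 - gt_a.  Missing fractions are those of
    the two core groups at panel construction.
    """

    species_a: str
    species_b: str
    chrom: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    gt_a: np.ndarray
    missing_a: np.ndarray
    missing_b: np.ndarray

    def __len__(self) -> int:
        return len(self.pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                             "allele_a": self.allele_a, "allele_b": self.allele_b,
                             "missing_a": self.missing_a, "missing_b": self.missing_b})


@dataclass
class AncestryPainting:
    sample_id: str
    maternal_species: str
    paternal_species: str
    site_classes: np.ndarray  # per panel site: 'hom_m', 'het', 'hom_p', 'missing'
    n_hom_m: int
    n_het: int
    n_hom_p: int
    hybrid_class: str | None = field(default=None)

    @property
    def n_called(self) -> int:
        return self.n_hom_m + self.n_het + self.n_hom_p

    @property
    def heterozygosity(self) -> float:
        return self.n_het / self.n_called

    @property
    def f_m_genome(self) -> float:
        return (2 * self.n_hom_m + self.n_het) / (2 * self.n_called)


def find_fixed_sites(gm: GenotypeMatrix, meta: pd.DataFrame, species_a: str,
                     species_b: str, max_missing: float = 0.2) -> FixedSitePanel:
    """Build the diagnostic panel for a species pair from core groups.

    A site enters the panel iff every called core-group genotype of A is
    homozygous for one allele, every called core-group genotype of B is
    homozygous for the other, and the missing fraction is <= ``max_missing``
    in each core group.  "Fixed" is judged on called genotypes only.
    """
    def core_idx(sp: str) -> np.ndarray:
        rows = meta[(meta["species"] == sp) & meta["core_group"].astype(bool)]
        if rows.empty:
            raise ValueError(f"no core-group samples for species {sp!r}")
        return gm.sample_indices(rows["sample_id"])

    ia, ib = core_idx(species_a), core_idx(species_b)
    ga, gb = gm.gt[:, ia], gm.gt[:, ib]
    miss_a = (ga < 0).mean(axis=1)
    miss_b = (gb < 0).mean(axis=1)
    called_a = (ga >= 0).any(axis=1)
    called_b = (gb >= 0).any(axis=1)

    def fixed_value(g: np.ndarray) -> np.ndarray:
        """Per site: 0 or 2 if all called genotypes are that homozygote,
        else -9."""
        called = g >= 0
        all0 = ((g == 0) | ~called).all(axis=1)
        all2 = ((g == 2) | ~called).all(axis=1)
        return np.where(all0, 0, np.where(all2, 2, -9))

    fa, fb = fixed_value(ga), fixed_value(gb)
    keep = (called_a & called_b & (miss_a <= max_missing) & (miss_b <= max_missing)
            & (fa >= 0) & (fb >= 0) & (fa != fb))
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        logger.warning("find_fixed_sites: empty panel for %s vs %s — hybrid detection impossible",
                       species_a, species_b)
    gt_a = fa[idx]
    allele_a = np.where(gt_a == 0, gm.ref[idx], gm.alt[idx])
    allele_b = np.where(gt_a == 0, gm.alt[idx], gm.ref[idx])
    return FixedSitePanel(species_a, species_b, gm.chrom[idx], gm.pos[idx],
                          allele_a, allele_b, gt_a.astype(np.int8),
                          miss_a[idx], miss_b[idx])


def paint(gm: GenotypeMatrix, panel: FixedSitePanel, sample_id: str,
          mito_species: str, min_called: int = 20) -> AncestryPainting:
    """Classify one putative hybrid at every panel site.

    ``mito_species`` orients the painting: it must be one of the panel's two
    species and is taken as the maternal side.  Requires at least
    ``min_called`` called panel sites.
    """
    if mito_species == panel.species_a:
        maternal, paternal = panel.species_a, panel.species_b
    elif mito_species == panel.species_b:
        maternal, paternal = panel.species_b, panel.species_a
    else:
        raise ValueError(
            f"mitochondrial species {mito_species!r} is neither {panel.species_a!r} "
            f"nor {panel.species_b!r}; painting undefined")

    j = gm.sample_indices([sample_id])[0]
    site_of = {(c, p): i for i, (c, p) in enumerate(zip(gm.chrom, gm.pos))}
    classes = np.empty(len(panel), dtype=object)
    n_hom_m = n_het = n_hom_p = 0
    maternal_gt = panel.gt_a if maternal == panel.species_a else 2 - panel.gt_a
    for k in range(len(panel)):
        i = site_of.get((panel.chrom[k], panel.pos[k]))
        g = gm.gt[i, j] if i is not None else -1
        if g < 0:
            classes[k] = "missing"
        elif g == 1:
            classes[k] = "het"
            n_het += 1
        elif g == maternal_gt[k]:
            classes[k] = "hom_m"
            n_hom_m += 1
        else:
            classes[k] = "hom_p"
            n_hom_p += 1
    called = n_hom_m + n_het + n_hom_p
    if called < min_called:
        raise ValueError(
            f"sample {sample_id!r} has only {called} called panel sites (< {min_called})")
    return AncestryPainting(sample_id, maternal, paternal, classes, n_hom_m, n_het, n_hom_p)


def classify_hybrid(p: AncestryPainting, f1_min_h: float = 0.9,
                    bc_h_range: tuple[float, float] = (0.3, 0.7)) -> str:
    """F1 if H >= ``f1_min_h``; backcross if H within ``bc_h_range``; else
    ambiguous (left for manual review).  The label is stored on the
    painting and returned."""
    h = p.heterozygosity
    if h >= f1_min_h:
        label = "F1"
    elif bc_h_range[0] <= h <= bc_h_range[1]:
        label = "backcross"
    else:
        label = "ambiguous"
    p.hybrid_class = label
    return label


def cohort_summary(paintings, meta: pd.DataFrame, n_analyzed: int | None = None) -> dict:
    """Cohort-level hybrid statistics.

    Returns hybrid counts per species pair and per sampling site, the
    overall hybrid frequency in percent (one decimal), and 0.05-binned
    histograms of H and f_m,genome.
    """
    paintings = list(paintings)
    n_analyzed = n_analyzed if n_analyzed is not None else len(meta)
    site_of = dict(zip(meta["sample_id"], meta.get("site", pd.Series(dtype=object))))
    pair_counts: dict[tuple[str, str], int] = {}
    site_counts: dict[str, int] = {}
    for p in paintings:
        pair = tuple(sorted((p.maternal_species, p.paternal_species)))
        pair_counts[pair] = pair_counts.get(pair, 0) + 1
        s = site_of.get(p.sample_id)
        if s is not None:
            site_counts[s] = site_counts.get(s, 0) + 1
    bins = np.round(np.arange(0.0, 1.0501, 0.05), 10)
    h_vals = np.array([p.heterozygosity for p in paintings])
    fm_vals = np.array([p.f_m_genome for p in paintings])
    freq_percent = round(100.0 * len(paintings) / n_analyzed, 1) if n_analyzed else 0.0
    return {
        "n_hybrids": len(paintings),
        "n_analyzed": n_analyzed,
        "overall_frequency_percent": freq_percent,
        "per_pair": {f"{a}+{b}": n for (a, b), n in sorted(pair_counts.items())},
        "per_site": dict(sorted(site_counts.items())),
        "h_histogram": np.histogram(h_vals, bins=bins)[0].tolist() if len(h_vals) else [],
        "f_m_histogram": np.histogram(fm_vals, bins=bins)[0].tolist() if len(fm_vals) else [],
        "histogram_bins": bins.tolist(),
    }


def paintings_to_frame(paintings) -> pd.DataFrame:
    rows = [{"sample_id": p.sample_id, "maternal_species": p.maternal_species,
             "paternal_species": p.paternal_species, "n_called": p.n_called,
             "n_hom_m": p.n_hom_m, "n_het": p.n_het, "n_hom_p": p.n_hom_p,
             "H": p.heterozygosity, "f_m_genome": p.f_m_genome,
             "hybrid_class": p.hybrid_class} for p in paintings]
    return pd.DataFrame(rows)


def plot_painting(painting: AncestryPainting, ax=None):
    """Horizontal bar-per-site painting (hom-maternal / het / hom-paternal)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1.2))
    colors = {"hom_m": "#2166ac", "het": "#99c457", "hom_p": "#b2182b", "missing": "#ffffff"}
    for k, cls in enumerate(painting.site_classes):
        ax.bar(k, 1.0, width=1.0, color=colors[cls], edgecolor="none")
    ax.set_xlim(-0.5, len(painting.site_classes) - 0.5)
    ax.set_yticks([])
    ax.set_title(f"{painting.sample_id}  H={painting.heterozygosity:.2f} "
                 f"f_m={painting.f_m_genome:.2f}", fontsize=8)
    return ax
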