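"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

import hybridscan as hs
from hybridscan.genotype_io import GenotypeMatrix


@pytest.fixture(scope="session")
def quartet_tree() -> hs.SpeciesTree:
    """Asymmetric 4-taxon tree (((P1,P2),P3),O) with moderate drift."""
    return hs.SpeciesTree.from_newick("(((P1:3,P2:3):4,P3:7):3,O:10);", ne=150_000)


@pytest.fixture(scope="session")
def eel_tree() -> hs.SpeciesTree:
    return hs.default_species_tree()


@pytest.fixture(scope="session")
def hybrid_cohort():
    """Genotypes + metadata for two species with F1 and BC1 hybrids."""
    tree = hs.SpeciesTree.from_newick("(A:5,B:5);", ne=120_000)
    freqs = hs.simulate_species_frequencies(tree, n_sites=4000, seed=11)
    pedigree = hs.PedigreeSpec.cohort(
        {"A": 12, "B": 12},
        [("F1", "A", "B", 10), ("BC1-maternal", "A", "B", 5), ("BC1-paternal", "A", "B", 5)])
    gm, meta = hs.simulate_genotypes(freqs, pedigree, missing_rate=0.05, seed=12)
    return freqs, gm, meta


def toy_matrix(gt, dp=None, gq=None, pos=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a genotype array (sites x samples)."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    dp = np.full(gt.shape, 20, dtype=np.int32) if dp is None else np.asarray(dp, np.int32)
    gq = np.full(gt.shape, 60, dtype=np.int32) if gq is None else np.asarray(gq, np.int32)
    pos = np.arange(1, n_sites + 1, dtype=np.int64) * 1000 if pos is None else np.asarray(pos, np.int64)
    return GenotypeMatrix(
        chrom=np.asarray(["chr1"] * n_sites, dtype=object), pos=pos,
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["T"] * n_sites, dtype=object),
        samples=[f"s{i}" for i in range(n_samples)], gt=gt, dp=dp, gq=gq)
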