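"""Generator correctness: drift kernel, pedigrees, coalescent, morphology."""

import numpy as np
import pandas as pd
import pytest

import hybridscan as hs
from hybridscan.synthetic_data import (EXPECTED_MATERNAL_FRACTION, SpeciesNode,
                                       _sample_gene_tree, default_morph_model)
from hybridscan.morphology import derive_measures, f_m_morphology, species_morph_summary


def zero_drift_tree(newick: str) -> hs.SpeciesTree:
    tree = hs.SpeciesTree.from_newick(newick)
    for node in tree.preorder():
        node.drift = 0.0
    return tree


class TestSpeciesTree:
    def test_default_tree_shape(self, eel_tree):
        assert len(eel_tree.tips()) == 7
        assert eel_tree.root.age == pytest.approx(13.76)
        assert eel_tree.mrca_age(["megastoma", "marmorata"]) == pytest.approx(9.7)
        assert eel_tree.mrca_age(["marmorata", "obscura"]) == pytest.approx(7.2023)

    def test_newick_roundtrip(self, eel_tree):
        again = hs.SpeciesTree.from_newick(eel_tree.to_newick())
        assert again.tips() == eel_tree.tips()
        assert again.root.age == pytest.approx(eel_tree.root.age, rel=1e-5)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric|age"):
            hs.SpeciesTree(SpeciesNode(age=2.0, children=[
                SpeciesNode("a", age=0.0), SpeciesNode("b", age=0.5)]))

    def test_admixture_must_postdate_divergence(self, quartet_tree):
        with pytest.raises(ValueError, match="predates"):
            hs.IntrogressionEdge("P1", "P3", 0.1, 8.0).validate(quartet_tree)
        hs.IntrogressionEdge("P1", "P3", 0.1, 3.0).validate(quartet_tree)


class TestFrequencies:
    def test_no_drift_identity(self):
        tree = zero_drift_tree("((A:1,B:1):1,C:2);")
        f = hs.simulate_species_frequencies(tree, n_sites=50, seed=0)
        assert np.allclose(f["A"], f["B"]) and np.allclose(f["A"], f["C"])

    def test_full_replacement(self):
        tree = hs.SpeciesTree.from_newick("((A:2,B:2):1,C:3);", ne=50_000)
        edge = hs.IntrogressionEdge("A", "B", alpha=1.0, time_ma=1e-6)
        f = hs.simulate_species_frequencies(tree, [edge], n_sites=400, seed=1)
        # drift after the event is negligible over 1 yr
        assert np.allclose(f["A"], f["B"], atol=0.01)

    def test_frequencies_in_unit_interval(self, eel_tree):
        f = hs.simulate_species_frequencies(eel_tree, n_sites=500, seed=2)
        assert float(f.min().min()) >= 0.0 and float(f.max().max()) <= 1.0

    def test_drift_moments_match_wright_fisher_oracle(self):
        """BN drift reproduces the WF variance E(p-p0)^2 = F p0(1-p0) and
        heterozygosity decay within MC error; sample-level fixed-difference
        fractions agree with forward WF only loosely (the Beta kernel has no
        fixation atoms), checked at a 25% relative band."""
        n, t_gens, g, n_sites = 50, 150, 10.0, 20_000
        tree = hs.SpeciesTree.from_newick(f"(A:{t_gens * g / 1e6},B:{t_gens * g / 1e6});",
                                          generation_time=g, ne=n)
        rng = np.random.default_rng(8)
        p0 = rng.uniform(0.05, 0.95, n_sites)
        pa, pb = p0.copy(), p0.copy()
        for _ in range(t_gens):  # forward Wright-Fisher oracle
            pa = rng.binomial(2 * n, pa) / (2 * n)
            pb = rng.binomial(2 * n, pb) / (2 * n)
        f = hs.simulate_species_frequencies(tree, n_sites=n_sites, seed=7,
                                            anc_range=(0.05, 0.95))
        a = f["A"].to_numpy()
        f_wf = float(np.mean((pa - p0) ** 2) / np.mean(p0 * (1 - p0)))
        f_expected = 1.0 - np.exp(-t_gens / (2 * n))
        assert f_wf == pytest.approx(1.0 - (1 - 1 / (2 * n)) ** t_gens, rel=0.05)
        # BN variance: E (p_A - p0')^2 with its own ancestral draws
        rng2 = np.random.default_rng(7)
        p0_bn = rng2.uniform(0.05, 0.95, n_sites)  # same seed stream as the generator
        f_bn = float(np.mean((a - p0_bn) ** 2) / np.mean(p0_bn * (1 - p0_bn)))
        assert f_bn == pytest.approx(f_expected, rel=0.03)

        def sample_fixed(x, y, k, rg):
            gx = rg.binomial(2, np.repeat(x[:, None], k, axis=1))
            gy = rg.binomial(2, np.repeat(y[:, None], k, axis=1))
            return float(np.mean(((gx == 0).all(1) & (gy == 2).all(1))
                                 | ((gx == 2).all(1) & (gy == 0).all(1))))

        fx_bn = sample_fixed(a, f["B"].to_numpy(), 8, np.random.default_rng(1))
        fx_wf = sample_fixed(pa, pb, 8, np.random.default_rng(1))
        assert fx_bn == pytest.approx(fx_wf, rel=0.25)

    def test_increasing_alpha_increases_downstream_d(self, quartet_tree):
        from hybridscan.introgression_stats import SiteFrequencies, compute_d

        ds = []
        for alpha in (0.0, 0.05, 0.2):
            edges = [hs.IntrogressionEdge("P3", "P2", alpha, 1.0)] if alpha else []
            means = []
            for seed in range(4):
                f = hs.simulate_species_frequencies(quartet_tree, edges, n_sites=4000,
                                                    seed=100 + seed)
                means.append(compute_d(SiteFrequencies.from_table(
                    f, "P1", "P2", "P3", "O")).d)
            ds.append(np.mean(means))
        assert ds[0] < ds[1] < ds[2]


class TestGenotypes:
    def test_f1_heterozygous_at_diagnostic_sites(self):
        freqs = pd.DataFrame({"A": np.zeros(200), "B": np.ones(200)})
        ped = hs.PedigreeSpec.cohort({}, [("F1", "A", "B", 3)])
        gm, _ = hs.simulate_genotypes(freqs, ped, missing_rate=0.0, seed=0)
        assert np.all(gm.gt == 1)

    def test_bc1_exact_pedigree_probabilities(self):
        """At a site fixed 0 maternal / 1 paternal, BC1-maternal genotypes
        are {hom-maternal: 1/2, het: 1/2}."""
        n = 10_000
        freqs = pd.DataFrame({"A": np.zeros(n), "B": np.ones(n)})
        ped = hs.PedigreeSpec.cohort({}, [("BC1-maternal", "A", "B", 1)])
        gm, _ = hs.simulate_genotypes(freqs, ped, missing_rate=0.0, seed=1)
        g = gm.gt[:, 0]
        assert set(np.unique(g)) <= {0, 1}
        frac_hom = float(np.mean(g == 0))
        assert frac_hom == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_no_missing_when_rate_zero(self, hybrid_cohort):
        freqs, _, _ = hybrid_cohort
        ped = hs.PedigreeSpec.cohort({"A": 3})
        gm, _ = hs.simulate_genotypes(freqs, ped, missing_rate=0.0, seed=5)
        assert not np.any(gm.gt < 0)

    def test_mito_label_is_maternal_for_all_hybrids(self, hybrid_cohort):
        _, _, meta = hybrid_cohort
        hyb = meta[meta["hybrid_status"] != "pure"]
        assert (hyb["mito_species"] == hyb["species"]).all()
        assert len(hyb) == 20

    def test_unknown_species_rejected(self):
        freqs = pd.DataFrame({"A": [0.5]})
        with pytest.raises(KeyError, match="unknown species"):
            hs.simulate_genotypes(freqs, hs.PedigreeSpec.cohort({"Z": 1}), seed=0)

    def test_seed_reproducibility(self, hybrid_cohort):
        freqs, gm, _ = hybrid_cohort
        ped = hs.PedigreeSpec.cohort({"A": 2, "B": 2})
        g1, _ = hs.simulate_genotypes(freqs, ped, seed=9)
        g2, _ = hs.simulate_genotypes(freqs, ped, seed=9)
        assert np.array_equal(g1.gt, g2.gt) and np.array_equal(g1.dp, g2.dp)


class TestLocusAlignments:
    def test_zero_ne_gene_tree_equals_species_tree(self, eel_tree):
        tree = hs.default_species_tree(ne=0.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = _sample_gene_tree(rng, tree, [])
            pair_time = _pairwise_time(g, "marmorata", "luzonensis")
            assert pair_time == pytest.approx(3.5e6 / tree.generation_time)
            assert _pairwise_time(g, "marmorata", "mossambica") == pytest.approx(
                13.76e6 / tree.generation_time)

    def test_ils_minor_topologies_match_closed_form(self):
        """Rooted triplet: each minor topology arises with probability
        (1/3) exp(-T / 2N), T the internal branch in generations."""
        g_years, ne = 10.0, 100_000.0
        tree = hs.SpeciesTree.from_newick("((A:1,B:1):1,C:2);", generation_time=g_years, ne=ne)
        t_internal = 1e6 / g_years
        expect = np.exp(-t_internal / (2 * ne)) / 3.0
        rng = np.random.default_rng(42)
        n = 3000
        counts = {"AB": 0, "AC": 0, "BC": 0}
        for _ in range(n):
            g = _sample_gene_tree(rng, tree, [])
            tab = _pairwise_time(g, "A", "B")
            tac = _pairwise_time(g, "A", "C")
            tbc = _pairwise_time(g, "B", "C")
            first = min((tab, "AB"), (tac, "AC"), (tbc, "BC"))[1]
            counts[first] += 1
        se = np.sqrt(expect * (1 - expect) / n)
        assert counts["AC"] / n == pytest.approx(expect, abs=4 * se)
        assert counts["BC"] / n == pytest.approx(expect, abs=4 * se)

    def test_ils_rate_cross_checked_against_msprime(self):
        """Independent oracle: msprime's MSC gives the same minor-topology
        frequency for the triplet as our sampler."""
        import msprime

        ne = 100_000
        demography = msprime.Demography()
        demography.add_population(name="A", initial_size=2 * ne)  # haploid lineages: rate 1/(2Ne)
        demography.add_population(name="B", initial_size=2 * ne)
        demography.add_population(name="C", initial_size=2 * ne)
        demography.add_population(name="AB", initial_size=2 * ne)
        demography.add_population(name="ABC", initial_size=2 * ne)
        demography.add_population_split(time=100_000, derived=["A", "B"], ancestral="AB")
        demography.add_population_split(time=200_000, derived=["AB", "C"], ancestral="ABC")
        n = 2000
        minor = 0
        reps = msprime.sim_ancestry({"A": 1, "B": 1, "C": 1}, demography=demography,
                                    ploidy=1, num_replicates=n, random_seed=7)
        for ts in reps:
            tree = ts.first()
            a, b, c = (int(ts.samples(population=i)[0]) for i in range(3))
            if tree.tmrca(a, c) < tree.tmrca(a, b) or tree.tmrca(b, c) < tree.tmrca(a, b):
                minor += 1
        ours_tree = hs.SpeciesTree.from_newick("((A:1,B:1):1,C:2);", generation_time=10.0, ne=ne)
        rng = np.random.default_rng(3)
        ours = 0
        for _ in range(n):
            g = _sample_gene_tree(rng, ours_tree, [])
            if min(_pairwise_time(g, "A", "C"), _pairwise_time(g, "B", "C")) \
                    < _pairwise_time(g, "A", "B"):
                ours += 1
        p1, p2 = minor / n, ours / n
        se = np.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
        assert p1 == pytest.approx(p2, abs=4 * max(se, 1e-3))

    def test_zero_rate_gives_identical_sequences(self, eel_tree):
        loci = hs.simulate_locus_alignments(eel_tree, n_loci=1, locus_length=50,
                                            seed=0, mutation_rate=0.0)
        assert len(np.unique(loci[0].codes, axis=0)) == 1

    def test_alignments_are_gap_free_and_sized(self, eel_tree):
        loci = hs.simulate_locus_alignments(eel_tree, n_loci=3, locus_length=120, seed=1)
        for aln in loci:
            assert aln.length == 120 and not np.any(aln.codes < 0)
            assert sorted(aln.taxa) == eel_tree.tips()

    def test_linked_blocks_cover_chromosome(self, quartet_tree):
        aln, tracts = hs.simulate_chromosome_alignment(quartet_tree, length=30_000,
                                                       tract_length=5_000, seed=4,
                                                       ingroups=["P1", "P2", "P3"])
        assert aln.length == 30_000
        assert tracts["start"].iloc[0] == 0 and tracts["end"].iloc[-1] == 30_000
        assert (tracts["end"].to_numpy()[:-1] == tracts["start"].to_numpy()[1:]).all()


class TestMorphology:
    def test_noise_free_f1_maps_to_half(self):
        model = default_morph_model(noise_scale=0.0)
        ped = hs.PedigreeSpec.cohort({"marmorata": 3, "megastoma": 3},
                                     [("F1", "marmorata", "megastoma", 1),
                                      ("BC1-maternal", "marmorata", "megastoma", 1)])
        raw = hs.simulate_morphology(model, ped, seed=0)
        records, rejected = derive_measures(raw)
        assert rejected.empty
        pure = records[records["category"] == "pure"]
        mat = species_morph_summary(
            pure[pure["maternal_species"] == "marmorata"].assign(species="marmorata"), "marmorata")
        pat = species_morph_summary(
            pure[pure["maternal_species"] == "megastoma"].assign(species="megastoma"), "megastoma")
        f1 = records[records["category"] == "F1"].iloc[0]
        bc = records[records["category"] == "BC1-maternal"].iloc[0]
        assert f_m_morphology(f1, mat, pat) == pytest.approx(0.5, abs=1e-9)
        assert f_m_morphology(bc, mat, pat) == pytest.approx(0.75, abs=1e-9)

    def test_noisy_recovery_slope_near_one(self):
        """Regressing recovered f_m,morphology on the true maternal fraction
        over 200 hybrids recovers slope ~ 1."""
        from scipy.stats import linregress

        model = default_morph_model(noise_scale=0.6)
        hybrids = [("F1", "marmorata", "megastoma", 70),
                   ("BC1-maternal", "marmorata", "megastoma", 65),
                   ("BC1-paternal", "marmorata", "megastoma", 65)]
        ped = hs.PedigreeSpec.cohort({"marmorata": 40, "megastoma": 40}, hybrids)
        raw = hs.simulate_morphology(model, ped, seed=3)
        records, _ = derive_measures(raw)  # carries category / truth columns through
        pure = records[records["category"] == "pure"]
        mat = species_morph_summary(
            pure[pure["maternal_species"] == "marmorata"].assign(species="m"), "m")
        pat = species_morph_summary(
            pure[pure["maternal_species"] == "megastoma"].assign(species="p"), "p")
        hyb = records[records["category"] != "pure"]
        fm = [f_m_morphology(row, mat, pat) for _, row in hyb.iterrows()]
        fit = linregress(hyb["true_maternal_fraction"].to_numpy(dtype=float), fm)
        assert fit.slope == pytest.approx(1.0, abs=0.15)

    def test_expected_fractions_table(self):
        assert EXPECTED_MATERNAL_FRACTION == {"F1": 0.5, "BC1-maternal": 0.75,
                                              "BC1-paternal": 0.25}


def _pairwise_time(gnode, a: str, b: str) -> float:
    """Coalescence time of two named tips in a gene tree."""
    def tips_below(n):
        if not n.children:
            return {n.name}
        return set().union(*(tips_below(c) for c in n.children))

    best = None
    stack = [gnode]
    while stack:
        n = stack.pop()
        if n.children:
            below = tips_below(n)
            if a in below and b in below:
                if best is None or n.time < best:
                    sides = [tips_below(c) for c in n.children]
                    split = any(a in s and b not in s for s in sides) and \
                        any(b in s and a not in s for s in sides)
                    if split:
                        best = n.time
            stack.extend(n.children)
    return best
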