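"""Likelihood engine oracles, constrained fits, and support counting."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.linalg import expm

import hybridscan as hs
from hybridscan.genealogy_interrogation import (LocusAlignment, SubstitutionModel,
                                                fit_constrained, gtr, interrogate, jc69,
                                                parse_topology, pruning_loglik)

# The three placements of interioris, rooted by the (megastoma, mossambica)
# outgroup clade.  Without outgroup taxa the three placements collapse to one
# unrooted topology and reversible-model likelihoods cannot separate them.
H1 = ("((((marmorata,luzonensis),interioris),(bicolor,obscura)),"
      "(megastoma,mossambica));")
H2 = ("(((marmorata,luzonensis),((bicolor,obscura),interioris)),"
      "(megastoma,mossambica));")
H3 = ("((((marmorata,luzonensis),(bicolor,obscura)),interioris),"
      "(megastoma,mossambica));")


def brute_force_loglik(aln: LocusAlignment, branches, model: SubstitutionModel) -> float:
    """Exhaustive summation over all internal-node state assignments for the
    fixed rooted shape ((a,b),(c,d)) (or (a,b) / ((a,b),c) for fewer taxa),
    with transition matrices from scipy.linalg.expm on an independently
    constructed GTR rate matrix."""
    freqs = model.freqs
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    q = np.zeros((4, 4))
    for r, (i, j) in zip(model.rates, pairs):
        q[i, j] = r * freqs[j]
        q[j, i] = r * freqs[i]
    np.fill_diagonal(q, -q.sum(1))
    q /= -(freqs * np.diag(q)).sum()
    p_of = {k: expm(q * t) for k, t in branches.items()}
    codes = aln.codes
    n_taxa = len(aln.taxa)
    total = 0.0
    for site in range(aln.length):
        obs = codes[:, site]

        def tip_term(p, taxon, state):
            if obs[taxon] < 0:
                return 1.0
            return p[state, obs[taxon]]

        site_l = 0.0
        if n_taxa == 2:
            for s in range(4):
                site_l += freqs[s] * tip_term(p_of["a"], 0, s) * tip_term(p_of["b"], 1, s)
        elif n_taxa == 3:
            for s_r in range(4):
                for s_x in range(4):
                    site_l += (freqs[s_r] * p_of["x"][s_r, s_x]
                               * tip_term(p_of["a"], 0, s_x) * tip_term(p_of["b"], 1, s_x)
                               * tip_term(p_of["c"], 2, s_r))
        else:
            for s_r in range(4):
                for s_x in range(4):
                    for s_y in range(4):
                        site_l += (freqs[s_r]
                                   * p_of["x"][s_r, s_x] * p_of["y"][s_r, s_y]
                                   * tip_term(p_of["a"], 0, s_x) * tip_term(p_of["b"], 1, s_x)
                                   * tip_term(p_of["c"], 2, s_y) * tip_term(p_of["d"], 3, s_y))
        total += math.log(site_l)
    return total


class TestPruningClosedForms:
    def test_identical_single_site_zero_length(self):
        aln = LocusAlignment.from_sequences("x", {"a": "A", "b": "A"})
        assert pruning_loglik(aln, "(a:0,b:0);") == pytest.approx(-math.log(4), abs=1e-12)

    def test_two_taxon_jc_closed_form(self):
        t = 0.17
        aln = LocusAlignment.from_sequences("x", {"a": "ACGTACGTAA", "b": "ACGTACGTAT"})
        lnl = pruning_loglik(aln, f"(a:{t / 2},b:{t / 2});")
        p_same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        p_diff = (1 - p_same) / 3
        expected = 9 * math.log(p_same / 4) + math.log(p_diff / 4)
        assert lnl == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("model_kind", ["jc", "gtr"])
    @pytest.mark.parametrize("seqs,topology,branches", [
        ({"a": "ACGTA", "b": "AAGTC"}, "(a:0.1,b:0.25);", {"a": 0.1, "b": 0.25}),
        ({"a": "ACG", "b": "ATG", "c": "GCG"}, "((a:0.1,b:0.2):0.15,c:0.3);",
         {"a": 0.1, "b": 0.2, "x": 0.15, "c": 0.3}),
        ({"a": "ACGTN", "b": "ACGT-", "c": "ACCTA", "d": "GCCTA"},
         "((a:0.05,b:0.1):0.2,(c:0.15,d:0.12):0.08);",
         {"a": 0.05, "b": 0.1, "x": 0.2, "c": 0.15, "d": 0.12, "y": 0.08}),
    ])
    def test_matches_exhaustive_enumeration(self, model_kind, seqs, topology, branches):
        aln = LocusAlignment.from_sequences("x", seqs)
        if model_kind == "jc":
            model = jc69()
        else:
            model = gtr([1.2, 3.4, 0.7, 0.9, 4.1, 1.0], [0.3, 0.2, 0.35, 0.15])
        lnl = pruning_loglik(aln, topology, subst_model=model)
        assert lnl == pytest.approx(brute_force_loglik(aln, branches, model), abs=1e-10)

    def test_taxon_relabeling_invariance(self):
        seqs = {"a": "ACGTAA", "b": "ACGTAT", "c": "ACCTAA", "d": "GGGTAA"}
        aln = LocusAlignment.from_sequences("x", seqs)
        lnl1 = pruning_loglik(aln, "((a:0.1,b:0.2):0.1,(c:0.3,d:0.1):0.2);")
        relabeled = {"w": seqs["a"], "x": seqs["b"], "y": seqs["c"], "z": seqs["d"]}
        aln2 = LocusAlignment.from_sequences("x", relabeled)
        lnl2 = pruning_loglik(aln2, "((w:0.1,x:0.2):0.1,(y:0.3,z:0.1):0.2);")
        assert lnl1 == pytest.approx(lnl2, abs=1e-12)

    def test_zero_length_alignment_rejected(self):
        aln = LocusAlignment("x", ["a", "b"], np.zeros((2, 0), dtype=np.int8))
        with pytest.raises(ValueError, match="zero-length"):
            pruning_loglik(aln, "(a:0.1,b:0.1);")


class TestConstrainedFit:
    def test_identical_sequences_tie_with_zero_branches(self):
        seqs = {t: "ACGTACGTAC" * 5 for t in ("a", "b", "c", "d")}
        aln = LocusAlignment.from_sequences("x", seqs)
        fits = [fit_constrained(aln, nwk, subst_model="JC") for nwk in (
            "((a,b),(c,d));", "((a,c),(b,d));", "((a,d),(b,c));")]
        lnls = [f.lnl for f in fits]
        assert max(lnls) - min(lnls) < 1e-6
        assert all(np.max(f.branch_lengths) < 1e-4 for f in fits)

    def test_deterministic_replicates(self, eel_tree):
        aln = hs.simulate_locus_alignments(eel_tree, n_loci=1, locus_length=300,
                                           seed=5, mutation_rate=1e-8)[0]
        nwk = "((((marmorata,luzonensis),(bicolor,obscura)),interioris),(megastoma,mossambica));"
        l1 = fit_constrained(aln, nwk, subst_model="GTR").lnl
        l2 = fit_constrained(aln, nwk, subst_model="GTR").lnl
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_generating_topology_preferred(self):
        """Loci simulated on the H3 species tree score at least as well
        under H3 as under either alternative."""
        tree = hs.default_species_tree(ne=50_000)
        loci = hs.simulate_locus_alignments(tree, n_loci=10, locus_length=2000,
                                            seed=8, mutation_rate=1e-8)
        wins = 0
        for aln in loci:
            lnls = {h: fit_constrained(aln, nwk, subst_model="JC").lnl
                    for h, nwk in (("H1", H1), ("H2", H2), ("H3", H3))}
            wins += lnls["H3"] >= lnls["H1"] - 0.01 and lnls["H3"] >= lnls["H2"] - 0.01
        assert wins >= 9


class TestInterrogate:
    @staticmethod
    def binomial_two_tailed_oracle(k: int, n: int) -> float:
        """Exact two-tailed p for a fair coin via rational tail summation."""
        half = Fraction(1, 2) ** n
        lo = min(k, n - k)
        tail = sum(math.comb(n, i) for i in range(lo + 1)) * half
        return float(2 * tail) if 2 * lo != n else 1.0

    def test_study_scale_imbalance_significant(self):
        """541 vs 685 informative loci reject a 50:50 split at p < 1e-4."""
        from scipy.stats import binomtest

        p = binomtest(541, 541 + 685, 0.5).pvalue
        assert p < 1e-4
        assert p == pytest.approx(self.binomial_two_tailed_oracle(541, 1226), rel=1e-9)

    def test_balanced_counts_give_p_one(self):
        from scipy.stats import binomtest

        assert binomtest(100, 200, 0.5).pvalue == 1.0
        assert self.binomial_two_tailed_oracle(100, 200) == 1.0

    def test_lineage_sorting_gives_balanced_minor_support(self):
        """Pure ILS: H1-vs-H2 support counts are statistically exchangeable."""
        tree = hs.default_species_tree(ne=250_000)
        loci = hs.simulate_locus_alignments(tree, n_loci=100, locus_length=500,
                                            seed=17, mutation_rate=1e-8)
        res = interrogate(loci, [("H1", H1), ("H2", H2), ("H3", H3)], subst_model="JC")
        row = res.pair_counts.query("hyp_a == 'H1' and hyp_b == 'H2'").iloc[0]
        assert row["n_support_a"] + row["n_support_b"] >= 15
        assert row["p_binomial"] > 0.01

    def test_introgression_imbalance_detected(self):
        """Gene flow between interioris and the (bicolor, obscura) clade
        shifts support toward H2."""
        tree = hs.default_species_tree(ne=250_000)
        edge = hs.IntrogressionEdge("interioris", "obscura", 0.35, 2.0)
        loci = hs.simulate_locus_alignments(tree, [edge], n_loci=100, locus_length=500,
                                            seed=18, mutation_rate=1e-8)
        res = interrogate(loci, [("H1", H1), ("H2", H2), ("H3", H3)], subst_model="JC")
        row = res.pair_counts.query("hyp_a == 'H1' and hyp_b == 'H2'").iloc[0]
        assert row["n_support_b"] > row["n_support_a"]
        assert row["p_binomial"] < 0.05

    def test_ternary_coordinates_inside_triangle(self):
        tree = hs.default_species_tree(ne=100_000)
        loci = hs.simulate_locus_alignments(tree, n_loci=5, locus_length=400,
                                            seed=19, mutation_rate=1e-8)
        res = interrogate(loci, [("H1", H1), ("H2", H2), ("H3", H3)], subst_model="JC")
        assert res.per_locus["x"].between(0, 1).all()
        assert res.per_locus["y"].between(0, math.sqrt(3) / 2 + 1e-9).all()

    def test_mismatched_taxa_rejected(self):
        aln = LocusAlignment.from_sequences("x", {"a": "ACGT", "b": "ACGT"})
        with pytest.raises(ValueError, match="do not match"):
            parse_topology("(a,c);", aln.taxa)
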