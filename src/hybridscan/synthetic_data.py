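"""Synthetic genotype, sequence, and morphology data with known ground truth.

Everything downstream of this module (ancestry painting, D/f4 statistics,
genealogy interrogation, window scans, morphology) can be exercised offline
on data generated here.  The generator emulates the statistical structure
the analyses assume:

* species-structured biallelic SNP frequencies produced by Balding-Nichols
  drift along a dated species tree, with optional admixture pulses that mix
  a recipient's frequencies toward a donor's;
* diploid genotypes for pure individuals and pedigree hybrids (F1 and
  first-generation backcrosses), with RAD-style missingness, per-genotype
  read depth and quality, and mitochondrial labels inherited maternally;
* per-locus sequence alignments whose gene trees are drawn under the
  multispecies coalescent within the species tree (lineages may switch
  populations at introgression events), then evolved under a reversible
  substitution model;
* bivariate species-specific morphology (the PDH/TL and AD/TL ratio plane),
  with hybrids placed at the pedigree-expected mixture of parental means.

All stochastic operations take an explicit integer seed; the same seed
yields byte-identical output.  Sites are unlinked by default; a linked-block
mode (tracts sharing one gene tree along a chromosome) exists for the
sliding-window topology tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .genealogy_interrogation import LocusAlignment, SubstitutionModel, jc69

__all__ = [
    "SpeciesNode",
    "SpeciesTree",
    "IntrogressionEdge",
    "SampleSpec",
    "PedigreeSpec",
    "DepthModel",
    "MorphModel",
    "default_species_tree",
    "default_morph_model",
    "simulate_species_frequencies",
    "simulate_genotypes",
    "simulate_locus_alignments",
    "simulate_chromosome_alignment",
    "simulate_morphology",
]

HYBRID_CATEGORIES = ("F1", "BC1-maternal", "BC1-paternal")
CATEGORIES = ("pure",) + HYBRID_CATEGORIES

#: Expected fraction of the genome inherited from the maternal species.
EXPECTED_MATERNAL_FRACTION = {"F1": 0.5, "BC1-maternal": 0.75, "BC1-paternal": 0.25}


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


@dataclass
class SpeciesNode:
    """Node of a dated species tree.

    ``age`` is in Ma (tips at 0).  ``ne`` is the diploid effective size of
    the branch above the node; ``drift`` optionally overrides the branch's
    total Balding-Nichols fixation index F directly (0 = no drift).
    """

    name: str | None = None
    age: float = 0.0
    children: list["SpeciesNode"] = field(default_factory=list)
    ne: float = 200_000.0
    drift: float | None = None

    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted, dated, bifurcating species tree with per-branch drift.

    Ages strictly decrease from root to tips and tips sit at age 0; a
    generation time (years) converts branch durations to generations for
    the coalescent and drift kernels.
    """

    def __init__(self, root: SpeciesNode, generation_time: float = 10.0):
        if generation_time <= 0:
            raise ValueError("generation time must be positive")
        self.root = root
        self.generation_time = generation_time
        self._validate()

    def _validate(self) -> None:
        names = []
        for node in self.preorder():
            if node.drift is not None and not (0 <= node.drift < 1 or node.drift == 1):
                raise ValueError("drift must be finite and in [0, 1]")
            if node.ne < 0 or not math.isfinite(node.age):
                raise ValueError("invalid node parameters")
            for c in node.children:
                if c.age >= node.age:
                    raise ValueError("node ages must strictly decrease from root to tips")
            if node.is_leaf():
                if node.name is None:
                    raise ValueError("unnamed tip")
                if abs(node.age) > 1e-9:
                    raise ValueError(f"tip {node.name!r} not at age 0 (tree not ultrametric)")
                names.append(node.name)
        if len(names) != len(set(names)):
            raise ValueError("duplicate tip names")

    # -- traversal helpers --

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def tips(self) -> list[str]:
        return sorted(n.name for n in self.preorder() if n.is_leaf())

    def internal_nodes(self) -> list[SpeciesNode]:
        return [n for n in self.preorder() if not n.is_leaf()]

    def tip_set(self, node: SpeciesNode) -> frozenset[str]:
        return frozenset(n.name for n in _subtree(node) if n.is_leaf())

    def mrca_age(self, names) -> float:
        """Age of the most recent common ancestor of the given tips."""
        target = set(names)
        unknown = target - set(self.tips())
        if unknown:
            raise KeyError(f"unknown species {sorted(unknown)}")
        best = None
        for node in self.preorder():
            if target <= self.tip_set(node):
                if best is None or node.age < best.age:
                    best = node
        assert best is not None
        return best.age

    # -- drift --

    def segment_fixation(self, node: SpeciesNode, dt_ma: float, parent_age: float) -> float:
        """Balding-Nichols F accumulated over ``dt_ma`` of the branch above
        ``node`` (whose full duration is ``parent_age - node.age``)."""
        if dt_ma <= 0:
            return 0.0
        if node.drift is not None:
            span = parent_age - node.age
            if span <= 0:
                return node.drift
            return 1.0 - (1.0 - node.drift) ** (dt_ma / span)
        if node.ne == 0:
            return 1.0
        gens = dt_ma * 1e6 / self.generation_time
        return 1.0 - math.exp(-gens / (2.0 * node.ne))

    # -- newick --

    @classmethod
    def from_newick(cls, newick: str, generation_time: float = 10.0,
                    ne: float = 200_000.0) -> "SpeciesTree":
        """Parse an ultrametric newick with branch lengths in Ma."""
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def height(n) -> float:
            if n.is_leaf():
                return 0.0
            return max(height(c) + (c.edge.length or 0.0) for c in n.child_nodes())

        def build(n, age: float) -> SpeciesNode:
            node = SpeciesNode(name=n.taxon.label.replace(" ", "_") if n.taxon else None,
                               age=age, ne=ne)
            for c in n.child_nodes():
                node.children.append(build(c, age - (c.edge.length or 0.0)))
            return node

        root_age = height(dtree.seed_node)
        root = build(dtree.seed_node, root_age)
        # snap tip ages to exactly zero (tolerate float noise in input)
        for n in _subtree(root):
            if n.is_leaf() and abs(n.age) < 1e-6:
                n.age = 0.0
        return cls(root, generation_time=generation_time)

    def to_newick(self) -> str:
        def fmt(node: SpeciesNode, parent_age: float | None) -> str:
            if node.is_leaf():
                s = node.name
            else:
                s = "(" + ",".join(fmt(c, node.age) for c in node.children) + ")"
            if parent_age is not None:
                s += f":{parent_age - node.age:.6g}"
            return s

        return fmt(self.root, None) + ";"


def _subtree(node: SpeciesNode):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def default_species_tree(ne: float = 200_000.0, generation_time: float = 10.0) -> SpeciesTree:
    """Seven-species tropical eel tree: root (mossambica divergence) dated
    13.76 Ma and the ingroup radiation at 9.7 Ma; the remaining node ages
    are round within-range values chosen for qualitative realism."""

    def tip(name: str) -> SpeciesNode:
        return SpeciesNode(name=name, age=0.0, ne=ne)

    mar_luz = SpeciesNode(age=3.5, ne=ne, children=[tip("marmorata"), tip("luzonensis")])
    bic_obs = SpeciesNode(age=4.5, ne=ne, children=[tip("bicolor"), tip("obscura")])
    quartet = SpeciesNode(age=7.2023, ne=ne, children=[mar_luz, bic_obs])
    ingroup = SpeciesNode(age=8.5, ne=ne, children=[tip("interioris"), quartet])
    clade = SpeciesNode(age=9.7, ne=ne, children=[tip("megastoma"), ingroup])
    root = SpeciesNode(age=13.76, ne=ne, children=[tip("mossambica"), clade])
    return SpeciesTree(root, generation_time=generation_time)


# ---------------------------------------------------------------------------
# Introgression edges and pedigrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntrogressionEdge:
    """Admixture pulse: at ``time_ma`` the recipient lineage receives a
    fraction ``alpha`` of its genome from the donor lineage."""

    donor: str
    recipient: str
    alpha: float
    time_ma: float

    def validate(self, tree: SpeciesTree) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        div = tree.mrca_age([self.donor, self.recipient])
        if self.time_ma >= div:
            raise ValueError(
                f"admixture at {self.time_ma} Ma predates the divergence "
                f"({div} Ma) of {self.donor} and {self.recipient}")
        if self.time_ma < 0:
            raise ValueError("admixture time must be >= 0")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    category: str
    maternal: str
    paternal: str
    population: str = "pop1"
    site: str = "site1"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "pure":
            if self.maternal != self.paternal:
                raise ValueError("pure samples must have maternal == paternal")
        elif self.maternal == self.paternal:
            raise ValueError(f"{self.category} requires maternal != paternal")


@dataclass
class PedigreeSpec:
    """Per-sample pedigree categories with maternal/paternal species.

    The mitochondrial label of every sample equals its maternal species.
    """

    samples: list[SampleSpec]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in pedigree")

    @classmethod
    def cohort(cls, pure: dict[str, int],
               hybrids: list[tuple[str, str, str, int]] = ()) -> "PedigreeSpec":
        """Build a pedigree from counts: ``pure`` maps species -> n samples;
        ``hybrids`` lists (category, maternal, paternal, n) tuples."""
        samples = []
        for sp, n in pure.items():
            for i in range(n):
                samples.append(SampleSpec(f"{sp}_{i:03d}", "pure", sp, sp))
        for cat, mat, pat, n in hybrids:
            for i in range(n):
                samples.append(SampleSpec(f"{cat}_{mat}x{pat}_{i:03d}", cat, mat, pat))
        return cls(samples)

    def species(self) -> set[str]:
        return {s.maternal for s in self.samples} | {s.paternal for s in self.samples}


@dataclass(frozen=True)
class DepthModel:
    """Poisson read depth with clipped-normal phred genotype quality."""

    mean_depth: float = 20.0
    gq_mean: float = 60.0
    gq_sd: float = 15.0


@dataclass
class MorphModel:
    """Bivariate species morphology on the (PDH/TL, AD/TL) ratio plane.

    ``means`` maps species to their mean ratio pair; ``cov`` is the common
    within-species covariance, scaled by ``noise_scale`` (0 = noise-free).
    The remaining fields generate the raw measurements (TL, HL) so the full
    measurement table can be derived downstream.
    """

    means: dict[str, tuple[float, float]]
    cov: np.ndarray = field(default_factory=lambda: np.array([[1.44e-4, 6.0e-5],
                                                              [6.0e-5, 1.0e-4]]))
    noise_scale: float = 1.0
    hl_tl: float = 0.11
    tl_mean: float = 600.0
    tl_sd: float = 120.0

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (2, 2) or not np.allclose(self.cov, self.cov.T):
            raise ValueError("cov must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-12):
            raise ValueError("cov must be positive semi-definite")
        for sp, m in self.means.items():
            if not np.all(np.isfinite(m)):
                raise ValueError(f"non-finite means for {sp}")


def default_morph_model(noise_scale: float = 1.0) -> MorphModel:
    """Plausible eel ratio means: long-finned species (megastoma,
    interioris) have large PDH/TL and AD/TL, short-finned species (obscura,
    bicolor) small ones."""
    means = {
        "marmorata": (0.155, 0.105),
        "luzonensis": (0.165, 0.115),
        "interioris": (0.185, 0.135),
        "megastoma": (0.205, 0.155),
        "bicolor": (0.090, 0.045),
        "obscura": (0.075, 0.030),
        "mossambica": (0.120, 0.070),
    }
    return MorphModel(means=means, noise_scale=noise_scale)


# ---------------------------------------------------------------------------
# Allele-frequency simulation
# ---------------------------------------------------------------------------


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """One Balding-Nichols drift step: Beta(p(1-F)/F, (1-p)(1-F)/F) for
    interior frequencies; 0 and 1 are absorbing; F=1 fixes by a coin flip."""
    if f <= 0:
        return p
    out = p.copy()
    interior = (p > 0) & (p < 1)
    if f >= 1.0:
        out[interior] = rng.random(interior.sum()) < p[interior]
        return out.astype(float)
    k = (1.0 - f) / f
    pi = p[interior]
    out[interior] = rng.beta(pi * k, (1.0 - pi) * k)
    return out


def simulate_species_frequencies(tree: SpeciesTree, edges=(), n_sites: int = 1000,
                                 seed: int = 0, anc_range=(0.05, 0.95)) -> pd.DataFrame:
    """Per-species derived-allele frequencies at independent sites.

    Each site draws an ancestral frequency uniformly from ``anc_range`` at
    the root, drifts along every branch by a Balding-Nichols kernel whose F
    accumulates with branch duration, and is mixed as
    (1 - alpha) * recipient + alpha * donor at each admixture event.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    edges = list(edges)
    for e in edges:
        e.validate(tree)
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(anc_range[0], anc_range[1], size=n_sites)

    # active lineages keyed by the node terminating their branch
    tipsets = {id(n): tree.tip_set(n) for n in tree.preorder()}
    state: dict[int, tuple[SpeciesNode, np.ndarray, float]] = {}
    for c in tree.root.children:
        state[id(c)] = (c, p0.copy(), tree.root.age)

    events: list[tuple[float, int, object]] = []
    for node in tree.internal_nodes():
        if node is not tree.root:
            events.append((node.age, 0, node))
    for e in edges:
        events.append((e.time_ma, 1, e))
    events.sort(key=lambda t: (-t[0], t[1]))

    def advance(key: int, to_age: float) -> None:
        node, p, t_last = state[key]
        f = tree.segment_fixation(node, t_last - to_age, _parent_age(tree, node))
        state[key] = (node, _bn_draw(rng, p, f), to_age)

    def lineage_of(tip: str) -> int:
        for key, (node, _, _) in state.items():
            if tip in tipsets[id(node)]:
                return key
        raise KeyError(tip)

    for age, kind, payload in events:
        if kind == 0:
            node = payload
            key = id(node)
            advance(key, age)
            _, p, _ = state.pop(key)
            for c in node.children:
                state[id(c)] = (c, p.copy(), age)
        else:
            e = payload
            kd, kr = lineage_of(e.donor), lineage_of(e.recipient)
            if kd == kr:
                raise ValueError("donor and recipient share a lineage at the event time")
            advance(kd, age)
            advance(kr, age)
            node_r, pr, t = state[kr]
            _, pd_, _ = state[kd]
            state[kr] = (node_r, (1.0 - e.alpha) * pr + e.alpha * pd_, t)

    out = {}
    for key, (node, p, t_last) in list(state.items()):
        advance(key, 0.0)
        node, p, _ = state[key]
        out[node.name] = p
    return pd.DataFrame(out)[sorted(out)]


def _parent_age(tree: SpeciesTree, child: SpeciesNode) -> float:
    for node in tree.preorder():
        if child in node.children:
            return node.age
    raise ValueError("node has no parent")


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_genotypes(freqs: pd.DataFrame, pedigree: PedigreeSpec,
                       missing_rate: float = 0.1,
                       depth_model: DepthModel | None = None,
                       seed: int = 0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw diploid genotypes for a pedigree from species allele frequencies.

    Pure individuals draw two alleles binomially from their species'
    frequencies; F1s draw one allele from each parent species; BC1s draw one
    allele from the backcross parent species and one from an F1 gamete (a
    fair per-site coin between the two grandparental species).  Depth and
    quality come from ``depth_model``; a fraction ``missing_rate`` of
    genotypes is set to missing.  The mitochondrial label of every sample is
    its maternal species.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    dm = depth_model or DepthModel()
    unknown = PedigreeSpec(pedigree.samples).species() - set(freqs.columns)
    if unknown:
        raise KeyError(f"pedigree references unknown species {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_sites = len(freqs)
    n_samples = len(pedigree.samples)

    gt = np.empty((n_sites, n_samples), dtype=np.int8)
    for j, s in enumerate(pedigree.samples):
        pm = freqs[s.maternal].to_numpy()
        pp = freqs[s.paternal].to_numpy()
        if s.category == "pure":
            gt[:, j] = rng.binomial(2, pm)
        elif s.category == "F1":
            gt[:, j] = rng.binomial(1, pm) + rng.binomial(1, pp)
        else:
            # F1 gamete: fair coin per site between the grandparental species
            coin = rng.random(n_sites) < 0.5
            gamete = np.where(coin, rng.binomial(1, pm), rng.binomial(1, pp))
            parent_p = pm if s.category == "BC1-maternal" else pp
            gt[:, j] = gamete + rng.binomial(1, parent_p)

    dp = rng.poisson(dm.mean_depth, size=gt.shape).astype(np.int32)
    gq = np.clip(np.round(rng.normal(dm.gq_mean, dm.gq_sd, size=gt.shape)), 0, 99).astype(np.int32)
    if missing_rate > 0:
        miss = rng.random(gt.shape) < missing_rate
        gt[miss] = MISSING
        dp[miss] = 0
        gq[miss] = 0

    pos = np.cumsum(rng.integers(500, 1500, size=n_sites)).astype(np.int64)
    base_idx = rng.integers(0, 4, size=n_sites)
    ref = _BASES[base_idx]
    alt = _BASES[(base_idx + rng.integers(1, 4, size=n_sites)) % 4]  # always != ref

    gm = GenotypeMatrix(np.asarray(["chr1"] * n_sites, dtype=object), pos,
                        ref.astype(object), alt.astype(object),
                        [s.sample_id for s in pedigree.samples], gt, dp, gq)
    meta = pd.DataFrame({
        "sample_id": [s.sample_id for s in pedigree.samples],
        "species": [s.maternal for s in pedigree.samples],
        "population": [s.population for s in pedigree.samples],
        "site": [s.site for s in pedigree.samples],
        "mito_species": [s.maternal for s in pedigree.samples],
        "core_group": [s.category == "pure" for s in pedigree.samples],
        "hybrid_status": [s.category for s in pedigree.samples],
        "paternal_species": [s.paternal for s in pedigree.samples],
    })
    return gm, meta


# ---------------------------------------------------------------------------
# Multispecies-coalescent gene trees and sequence evolution
# ---------------------------------------------------------------------------


class _GNode:
    __slots__ = ("name", "children", "time")

    def __init__(self, name=None, children=(), time=0.0):
        self.name = name
        self.children = list(children)
        self.time = time  # generations before present


def _coalesce_all(lineages: list[_GNode], time: float) -> list[_GNode]:
    while len(lineages) > 1:
        a = lineages.pop()
        b = lineages.pop()
        lineages.append(_GNode(children=(a, b), time=time))
    return lineages


def _sample_gene_tree(rng: np.random.Generator, tree: SpeciesTree, edges,
                      samples_per_species: int = 1) -> _GNode:
    """Structured-coalescent gene tree within the species tree.

    Times are in generations.  At an admixture event, each lineage currently
    in the recipient population switches to the donor population with
    probability alpha (tracing ancestry backward in time).  Populations with
    ne == 0 coalesce instantly, so with no admixture the gene tree then
    equals the species tree.
    """
    g = tree.generation_time
    to_gens = 1e6 / g
    pops: dict[int, list[_GNode]] = {}
    for node in tree.preorder():
        if node.is_leaf():
            pops[id(node)] = [
                _GNode(name=node.name if samples_per_species == 1 else f"{node.name}_{i}",
                       time=0.0)
                for i in range(samples_per_species)]

    nodes_by_id = {id(n): n for n in tree.preorder()}
    tipsets = {id(n): tree.tip_set(n) for n in tree.preorder()}

    events: list[tuple[float, int, object]] = []
    for node in tree.internal_nodes():
        events.append((node.age * to_gens, 1, node))
    for e in edges:
        events.append((e.time_ma * to_gens, 0, e))
    events.sort(key=lambda t: (t[0], t[1]))

    def pop_key_of(tip: str) -> int:
        for key in pops:
            if tip in tipsets[key]:
                return key
        raise KeyError(tip)

    def coalesce_interval(key: int, t0: float, t1: float) -> None:
        lin = pops[key]
        ne = nodes_by_id[key].ne
        if len(lin) < 2:
            return
        if ne == 0:
            _coalesce_all(lin, t0)
            return
        t = t0
        while len(lin) > 1:
            k = len(lin)
            rate = k * (k - 1) / 2.0 / (2.0 * ne)
            t = t + rng.exponential(1.0 / rate)
            if t >= t1:
                return
            i, j = sorted(rng.choice(k, size=2, replace=False))
            b = lin.pop(j)
            a = lin.pop(i)
            lin.append(_GNode(children=(a, b), time=t))

    t_prev = 0.0
    for t_ev, kind, payload in events:
        for key in list(pops):
            coalesce_interval(key, t_prev, t_ev)
        if kind == 1:
            node = payload
            merged: list[_GNode] = []
            for c in node.children:
                merged.extend(pops.pop(id(c)))
            pops[id(node)] = merged
            if node.ne == 0 and len(merged) > 1 and node is not tree.root:
                _coalesce_all(merged, t_ev)
        else:
            e = payload
            kr, kd = pop_key_of(e.recipient), pop_key_of(e.donor)
            if kr != kd:
                moving = [ln for ln in pops[kr] if rng.random() < e.alpha]
                pops[kr] = [ln for ln in pops[kr] if ln not in moving]
                pops[kd].extend(moving)
        t_prev = t_ev

    root_key = id(tree.root)
    lin = pops[root_key]
    if tree.root.ne == 0:
        _coalesce_all(lin, t_prev)
    else:
        coalesce_interval(root_key, t_prev, math.inf)
    return lin[0]


def _evolve_on_gene_tree(rng: np.random.Generator, gtree: _GNode, length: int,
                         mutation_rate: float, model: SubstitutionModel) -> dict[str, np.ndarray]:
    """Evolve ``length`` sites down the gene tree; branch lengths are
    (parent time - child time) * mutation_rate expected substitutions."""
    root_states = rng.choice(4, size=length, p=model.freqs)
    seqs: dict[str, np.ndarray] = {}

    def walk(node: _GNode, states: np.ndarray) -> None:
        if not node.children:
            seqs[node.name] = states
            return
        for child in node.children:
            t = (node.time - child.time) * mutation_rate
            if t <= 0:
                walk(child, states.copy())
                continue
            p = model.p_matrix(t)
            cum = np.cumsum(p, axis=1)
            u = rng.random(length)
            child_states = np.empty(length, dtype=np.int8)
            for s in range(4):
                mask = states == s
                if mask.any():
                    child_states[mask] = np.searchsorted(cum[s], u[mask])
            walk(child, np.minimum(child_states, 3))

    walk(gtree, root_states.astype(np.int8))
    return seqs


def simulate_locus_alignments(tree: SpeciesTree, edges=(), n_loci: int = 100,
                              locus_length: int = 300,
                              subst_model: SubstitutionModel | None = None,
                              seed: int = 0, mutation_rate: float = 5e-9,
                              samples_per_species: int = 1) -> list[LocusAlignment]:
    """Gap-free per-locus alignments: one multispecies-coalescent gene tree
    per locus, sequences evolved under a reversible substitution model.

    ``mutation_rate`` is per site per generation; divergence in expected
    substitutions is gene-tree branch length (generations) times this rate.
    """
    if locus_length < 1 or n_loci < 1:
        raise ValueError("n_loci and locus_length must be >= 1")
    edges = list(edges)
    for e in edges:
        e.validate(tree)
    model = subst_model or jc69()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_loci):
        gtree = _sample_gene_tree(rng, tree, edges, samples_per_species)
        seqs = _evolve_on_gene_tree(rng, gtree, locus_length, mutation_rate, model)
        taxa = sorted(seqs)
        codes = np.vstack([seqs[t] for t in taxa]).astype(np.int8)
        out.append(LocusAlignment(f"locus_{i:05d}", taxa, codes))
    return out


def _ingroup_sister_pair(gtree: _GNode, ingroups: list[str]) -> tuple[str, str]:
    """The ingroup pair with the most recent coalescence in the gene tree."""
    times: dict[frozenset, float] = {}

    def walk(node: _GNode) -> set[str]:
        if not node.children:
            return {node.name} if node.name in ingroups else set()
        below = [walk(c) for c in node.children]
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for x in below[a]:
                    for y in below[b]:
                        times.setdefault(frozenset((x, y)), node.time)
        return set().union(*below)

    walk(gtree)
    pair = min((fs for fs in times if len(fs) == 2), key=lambda fs: times[fs])
    return tuple(sorted(pair))


def simulate_chromosome_alignment(tree: SpeciesTree, edges=(), length: int = 500_000,
                                  tract_length: float = 20_000.0,
                                  subst_model: SubstitutionModel | None = None,
                                  seed: int = 0, mutation_rate: float = 5e-9,
                                  scaffold: str = "scf1",
                                  ingroups: list[str] | None = None
                                  ) -> tuple[LocusAlignment, pd.DataFrame]:
    """Linked-block chromosome: contiguous tracts share one gene tree.

    Tract lengths are exponential with mean ``tract_length`` (min 1 bp).
    Returns the concatenated alignment plus a truth table with 0-based
    half-open tract coordinates and the realized sister pair among
    ``ingroups`` (default: all taxa except the last alphabetically).
    """
    edges = list(edges)
    for e in edges:
        e.validate(tree)
    model = subst_model or jc69()
    rng = np.random.default_rng(seed)
    taxa = sorted(tree.tips())
    ing = ingroups if ingroups is not None else taxa[:-1]
    chunks: list[np.ndarray] = []
    rows = []
    start = 0
    while start < length:
        tl = max(1, int(round(rng.exponential(tract_length))))
        end = min(length, start + tl)
        gtree = _sample_gene_tree(rng, tree, edges, 1)
        seqs = _evolve_on_gene_tree(rng, gtree, end - start, mutation_rate, model)
        chunks.append(np.vstack([seqs[t] for t in taxa]))
        pair = _ingroup_sister_pair(gtree, ing)
        rows.append({"scaffold": scaffold, "start": start, "end": end,
                     "sister_pair": "+".join(pair)})
        start = end
    aln = LocusAlignment(scaffold, taxa, np.hstack(chunks).astype(np.int8))
    return aln, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Morphology simulation
# ---------------------------------------------------------------------------


def simulate_morphology(model: MorphModel, pedigree: PedigreeSpec, seed: int = 0) -> pd.DataFrame:
    """Raw morphology table (TL, PA, PD, HL) for a pedigree.

    Pure individuals scatter around their species' mean (PDH/TL, AD/TL);
    hybrids around f * maternal + (1 - f) * paternal where f is the
    pedigree-expected maternal fraction (0.5 F1, 0.75/0.25 BC1).  The raw
    measurements are reconstructed from the ratios so the measurement
    identities (AD = PA - PD, PDH = PD - HL, ...) hold by construction.
    """
    rng = np.random.default_rng(seed)
    unknown = pedigree.species() - set(model.means)
    if unknown:
        raise KeyError(f"no morphology means for species {sorted(unknown)}")
    cov = model.noise_scale ** 2 * model.cov
    rows = []
    for s in pedigree.samples:
        f = 1.0 if s.category == "pure" else EXPECTED_MATERNAL_FRACTION[s.category]
        mu = f * np.asarray(model.means[s.maternal]) + (1 - f) * np.asarray(model.means[s.paternal])
        pdh_tl, ad_tl = rng.multivariate_normal(mu, cov, method="svd") if model.noise_scale > 0 else mu
        pdh_tl = max(pdh_tl, 0.005)
        ad_tl = max(ad_tl, 0.005)
        tl = max(100.0, rng.normal(model.tl_mean, model.tl_sd))
        hl = model.hl_tl * tl
        pd_ = pdh_tl * tl + hl
        pa = pd_ + ad_tl * tl
        rows.append({"sample_id": s.sample_id, "category": s.category,
                     "maternal_species": s.maternal, "paternal_species": s.paternal,
                     "true_maternal_fraction": f if s.category != "pure" else np.nan,
                     "TL": tl, "PA": pa, "PD": pd_, "HL": hl})
    return pd.DataFrame(rows)
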