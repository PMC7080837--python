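"""Per-locus genealogy interrogation.

Given a set of locus alignments and a small number of competing, fully
resolved topological hypotheses, this module computes the maximum-likelihood
score of every hypothesis for every locus (topology fixed, branch lengths and
substitution-model parameters free), counts which hypothesis each locus
supports, and tests whether the support counts for a pair of hypotheses are
compatible with a 50:50 split.  Under incomplete lineage sorting alone the
two minor topologies of a rooted triplet are equally probable, so a
significant imbalance between them is evidence of introgression.

The likelihood engine is a standard pruning (post-order conditional
likelihood) implementation for reversible nucleotide models; JC69 and GTR
with empirical base frequencies are supported.  Gaps and ambiguous bases are
treated as missing data (all-ones partial likelihoods).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import binomtest

__all__ = [
    "LocusAlignment",
    "SubstitutionModel",
    "jc69",
    "gtr",
    "parse_topology",
    "pruning_loglik",
    "fit_constrained",
    "ConstrainedFit",
    "interrogate",
    "InterrogationResult",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(["A", "C", "G", "T"])

# Branch-length box for the bounded scalar optimizer, in expected
# substitutions per site.  5 is far beyond saturation for within-genus data.
_BLEN_MIN = 1e-9
_BLEN_MAX = 5.0


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class LocusAlignment:
    """A gap-aware nucleotide alignment for one locus.

    ``codes`` holds one row per taxon with A,C,G,T encoded as 0..3 and
    anything else (gap, N, ambiguity) as -1.
    """

    locus_id: str
    taxa: list[str]
    codes: np.ndarray  # int8, shape (n_taxa, length)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, length)")

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, locus_id: str, seqs: dict[str, str]) -> "LocusAlignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        arr = np.full((len(taxa), lengths.pop()), -1, dtype=np.int8)
        for i, t in enumerate(taxa):
            for j, ch in enumerate(seqs[t].upper()):
                arr[i, j] = _CODE.get(ch, -1)
        return cls(locus_id, taxa, arr)

    @classmethod
    def from_fasta(cls, path, locus_id: str | None = None) -> "LocusAlignment":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(locus_id or str(path), seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in self.sequences.items():
                fh.write(f">{t}\n{s}\n")

    @property
    def sequences(self) -> dict[str, str]:
        out = {}
        for i, t in enumerate(self.taxa):
            chars = np.where(self.codes[i] >= 0, _BASES[np.clip(self.codes[i], 0, 3)], "N")
            out[t] = "".join(chars)
        return out

    def subset(self, taxa: list[str]) -> "LocusAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return LocusAlignment(self.locus_id, list(taxa), self.codes[idx])

    def window(self, start: int, end: int) -> "LocusAlignment":
        """Columns [start, end) as a new alignment (0-based, half-open)."""
        return LocusAlignment(f"{self.locus_id}:{start}-{end}", list(self.taxa), self.codes[:, start:end])


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------


class SubstitutionModel:
    """Time-reversible nucleotide model defined by GTR exchangeabilities and
    stationary base frequencies, normalized to one expected substitution per
    unit branch length."""

    def __init__(self, rates, freqs):
        rates = np.asarray(rates, dtype=float)
        freqs = np.asarray(freqs, dtype=float)
        if rates.shape != (6,) or np.any(rates < 0):
            raise ValueError("rates must be 6 non-negative exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("freqs must be 4 positive frequencies")
        freqs = freqs / freqs.sum()
        self.rates = rates
        self.freqs = freqs
        q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(rates, pairs):
            q[i, j] = r * freqs[j]
            q[j, i] = r * freqs[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(freqs, np.diag(q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        q /= mu
        # Symmetrize for a stable eigendecomposition of the reversible Q.
        sp = np.sqrt(freqs)
        s = (sp[:, None] * q) / sp[None, :]
        w, u = np.linalg.eigh((s + s.T) / 2.0)
        self._w = w
        self._left = u.T * sp[None, :]
        self._right = u / sp[:, None]

    def p_matrix(self, t: float) -> np.ndarray:
        """Transition probabilities after t expected substitutions/site."""
        if t < 0:
            raise ValueError("negative branch length")
        p = (self._right * np.exp(self._w * t)) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def jc69() -> SubstitutionModel:
    return SubstitutionModel(np.ones(6), np.full(4, 0.25))


def gtr(rates, freqs) -> SubstitutionModel:
    return SubstitutionModel(rates, freqs)


# ---------------------------------------------------------------------------
# Topologies
# ---------------------------------------------------------------------------


@dataclass
class _TreeArrays:
    """Rooted topology in postorder arrays for the pruning recursion."""

    children: list[list[int]]
    parent: np.ndarray
    postorder: np.ndarray
    leaf_index: dict[str, int]
    blen: np.ndarray
    root: int

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def free_branches(self) -> np.ndarray:
        """Indices of branches to optimize: every non-root node, except that
        for a bifurcating root one of the two root-child branches is pinned
        at zero (the two are confounded under a reversible model)."""
        free = [i for i in self.postorder if i != self.root]
        kids = self.children[self.root]
        if len(kids) == 2:
            pinned = kids[1]
            self.blen[pinned] = 0.0
            free = [i for i in free if i != pinned]
        return np.asarray(free)


def parse_topology(newick: str, taxa: list[str] | None = None) -> _TreeArrays:
    """Parse a (rooted, resolved) newick topology into pruning arrays.

    Branch lengths in the string are kept; absent lengths default to 0.1.
    If ``taxa`` is given the leaf set must match it exactly.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    children: list[list[int]] = [[] for _ in nodes]
    parent = np.full(len(nodes), -1, dtype=int)
    blen = np.zeros(len(nodes))
    leaf_index: dict[str, int] = {}
    for n in nodes:
        i = index[id(n)]
        blen[i] = n.edge.length if n.edge.length is not None else 0.1
        for c in n.child_nodes():
            children[i].append(index[id(c)])
            parent[index[id(c)]] = i
        if n.is_leaf():
            name = n.taxon.label.replace(" ", "_") if n.taxon else None
            if name is None:
                raise ValueError("unnamed leaf in topology")
            leaf_index[name] = i
    root = index[id(tree.seed_node)]
    if taxa is not None and set(leaf_index) != set(taxa):
        raise ValueError(
            f"topology taxa {sorted(leaf_index)} do not match alignment taxa {sorted(taxa)}"
        )
    return _TreeArrays(children, parent, np.asarray([index[id(n)] for n in nodes]), leaf_index, blen, root)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def _compress(aln: LocusAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their counts."""
    if aln.length == 0:
        raise ValueError("zero-length alignment")
    patterns, counts = np.unique(aln.codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class _PruningEngine:
    """Pruning recursion with tip partials precomputed for one alignment's
    site patterns, so repeated likelihood evaluations during optimization
    only redo the internal passes."""

    def __init__(self, tree: _TreeArrays, patterns: np.ndarray, taxa: list[str]):
        self.tree = tree
        self.npat = patterns.shape[1]
        row_of = {t: i for i, t in enumerate(taxa)}
        self.tip_partial: dict[int, np.ndarray] = {}
        for name, node in tree.leaf_index.items():
            codes = patterns[row_of[name]]
            lp = np.zeros((4, self.npat))
            obs = codes >= 0
            lp[:, ~obs] = 1.0
            lp[codes[obs], np.nonzero(obs)[0]] = 1.0
            self.tip_partial[node] = lp
        self.internal = [n for n in tree.postorder if tree.children[n]]

    def pattern_loglik(self, model: SubstitutionModel) -> np.ndarray:
        """Per-pattern log-likelihood at the current tree.blen."""
        tree = self.tree
        partial: dict[int, np.ndarray] = dict(self.tip_partial)
        logscale = np.zeros(self.npat)
        for node in self.internal:
            acc = None
            for c in tree.children[node]:
                term = model.p_matrix(tree.blen[c]) @ partial[c]
                acc = term if acc is None else acc * term
            mx = acc.max(axis=0)
            mx[mx == 0] = 1.0
            logscale += np.log(mx)
            partial[node] = acc / mx
        site_l = model.freqs @ partial[tree.root]
        return np.log(np.maximum(site_l, 1e-300)) + logscale


def _pattern_loglik(tree: _TreeArrays, patterns: np.ndarray, taxa: list[str],
                    model: SubstitutionModel) -> np.ndarray:
    return _PruningEngine(tree, patterns, taxa).pattern_loglik(model)


def pruning_loglik(aln: LocusAlignment, topology, branch_lengths=None,
                   subst_model: SubstitutionModel | None = None) -> float:
    """Total log-likelihood of an alignment on a fixed topology.

    ``topology`` is a newick string (or a pre-parsed tree); branch lengths
    come from the newick unless ``branch_lengths`` overrides them — either a
    mapping from leaf name to terminal branch length plus ``"_internal"``
    defaults, or a sequence assigned to non-root nodes in postorder.
    """
    model = subst_model or jc69()
    tree = topology if isinstance(topology, _TreeArrays) else parse_topology(topology, aln.taxa)
    if branch_lengths is not None:
        seq = np.asarray(branch_lengths, dtype=float)
        nonroot = [i for i in tree.postorder if i != tree.root]
        if seq.shape != (len(nonroot),):
            raise ValueError(f"expected {len(nonroot)} branch lengths")
        if np.any(seq < 0):
            raise ValueError("negative branch length")
        tree.blen[nonroot] = seq
    patterns, counts = _compress(aln)
    return float(_pattern_loglik(tree, patterns, aln.taxa, model) @ counts)


# ---------------------------------------------------------------------------
# Constrained optimization
# ---------------------------------------------------------------------------


@dataclass
class ConstrainedFit:
    lnl: float
    branch_lengths: np.ndarray
    model: SubstitutionModel
    tree: _TreeArrays = field(repr=False)


def _empirical_freqs(aln: LocusAlignment) -> np.ndarray:
    counts = np.bincount(aln.codes[aln.codes >= 0].ravel(), minlength=4).astype(float)
    return (counts + 1.0) / (counts.sum() + 4.0)


def fit_constrained(aln: LocusAlignment, topology, subst_model: str = "GTR",
                    max_sweeps: int = 20, rel_tol: float = 1e-6) -> ConstrainedFit:
    """Maximize the likelihood of a fixed topology over branch lengths (and,
    for GTR, exchangeabilities) by coordinate-wise bounded optimization.

    Base frequencies are empirical per locus.  Deterministic: no random
    starts, fixed sweep order, bounded Brent on each coordinate.
    """
    tree = topology if isinstance(topology, _TreeArrays) else parse_topology(topology, aln.taxa)
    patterns, counts = _compress(aln)
    taxa = aln.taxa
    freqs = _empirical_freqs(aln) if subst_model.upper() == "GTR" else np.full(4, 0.25)
    rates = np.ones(6)
    model = SubstitutionModel(rates, freqs)
    tree.blen[:] = np.minimum(np.maximum(tree.blen, 0.01), 1.0)
    tree.blen[tree.root] = 0.0  # the root carries no branch
    free = tree.free_branches()
    engine = _PruningEngine(tree, patterns, taxa)

    def total(m: SubstitutionModel) -> float:
        return float(engine.pattern_loglik(m) @ counts)

    def opt_branch(i: int, m: SubstitutionModel) -> None:
        def nll(t: float) -> float:
            tree.blen[i] = t
            return -total(m)

        res = minimize_scalar(nll, bounds=(_BLEN_MIN, _BLEN_MAX), method="bounded",
                              options={"xatol": 1e-9})
        tree.blen[i] = res.x

    lnl = total(model)
    for _ in range(max_sweeps):
        prev = lnl
        for i in free:
            opt_branch(i, model)
        if subst_model.upper() == "GTR":
            for k in range(5):  # GT exchangeability fixed at 1 as reference
                def nll_rate(logr: float, k=k) -> float:
                    r = rates.copy()
                    r[k] = 10.0 ** logr
                    return -total(SubstitutionModel(r, freqs))

                res = minimize_scalar(nll_rate, bounds=(-3.0, 3.0), method="bounded",
                                      options={"xatol": 1e-6})
                rates[k] = 10.0 ** res.x
            model = SubstitutionModel(rates, freqs)
        lnl = total(model)
        if abs(lnl - prev) <= rel_tol * max(1.0, abs(lnl)):
            break
    return ConstrainedFit(lnl, tree.blen.copy(), model, tree)


# ---------------------------------------------------------------------------
# Interrogation
# ---------------------------------------------------------------------------

# Ternary vertices: hypotheses are placed at the corners of an equilateral
# triangle; each locus sits at the support-weighted barycenter.
_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3.0) / 2.0]])


@dataclass
class InterrogationResult:
    per_locus: pd.DataFrame
    pair_counts: pd.DataFrame
    hypotheses: list[str]


def interrogate(loci, hypotheses, subst_model: str = "GTR", tie_tol: float = 0.01,
                cap: float = 10.0) -> InterrogationResult:
    """Score every locus under every hypothesis and summarize support.

    ``hypotheses`` maps hypothesis names to newick topologies (dict or list
    of (name, newick) pairs; exactly three are required for the ternary
    coordinates).  A locus supports hypothesis a over b iff
    lnL_a - lnL_b > tie_tol; pairs within tie_tol are uninformative.  For
    each ordered pair a two-tailed exact binomial test of a 50:50 split is
    reported, which is the null expected under incomplete lineage sorting.
    """
    if isinstance(hypotheses, dict):
        hyp = list(hypotheses.items())
    else:
        hyp = list(hypotheses)
    names = [n for n, _ in hyp]
    if len(names) != len(set(names)):
        raise ValueError("duplicate hypothesis names")
    loci = list(loci)
    if not loci:
        raise ValueError("no loci")
    rows = []
    for aln in loci:
        rec: dict[str, object] = {"locus": aln.locus_id}
        ok = True
        for name, nwk in hyp:
            try:
                fit = fit_constrained(aln, nwk, subst_model=subst_model)
                rec[f"lnl_{name}"] = fit.lnl
            except Exception as exc:  # optimization failure: locus excluded
                rec[f"lnl_{name}"] = np.nan
                rec["error"] = str(exc)
                ok = False
        rec["ok"] = ok
        rows.append(rec)
    per_locus = pd.DataFrame(rows)
    lnl = per_locus[[f"lnl_{n}" for n in names]].to_numpy()

    if len(names) == 3:
        best = lnl.max(axis=1, keepdims=True)
        support = np.maximum(0.0, cap - np.minimum(cap, best - lnl))
        tot = support.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        xy = (support / tot) @ _VERTICES
        per_locus["x"], per_locus["y"] = xy[:, 0], xy[:, 1]

    pair_rows = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            delta = lnl[:, i] - lnl[:, j]
            valid = np.isfinite(delta)
            n_a = int(np.sum(valid & (delta > tie_tol)))
            n_b = int(np.sum(valid & (delta < -tie_tol)))
            p = binomtest(n_a, n_a + n_b, 0.5).pvalue if n_a + n_b > 0 else np.nan
            pair_rows.append({"hyp_a": a, "hyp_b": b, "n_support_a": n_a,
                              "n_support_b": n_b, "n_uninformative": int(valid.sum()) - n_a - n_b,
                              "p_binomial": p})
    return InterrogationResult(per_locus, pd.DataFrame(pair_rows), names)
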