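"""Frequency-weighted ABBA/BABA (Patterson's D) and f4 statistics.

For a species quartet (((P1, P2), P3), outgroup) the per-site pattern
weights are, with p_i the derived-allele frequency in population i,

    ABBA = (1 - p1) * p2 * p3 * (1 - p4)
    BABA = p1 * (1 - p2) * p3 * (1 - p4)

summed over sites into C_ABBA and C_BABA, giving

    D = (C_ABBA - C_BABA) / (C_ABBA + C_BABA),

zero in expectation under incomplete lineage sorting alone.  The f4
statistic is the mean over sites of (p1 - p2) * (p3 - p4); its significance
is assessed against a no-admixture null simulated under per-branch drift on
the quartet tree, after a burnin that adjusts the branch drift so the
simulated pairwise allele-frequency dissimilarities match the observed
ones.  Alleles are polarized so that the allele rare in the outgroup is
derived; sites with a polymorphic outgroup contribute through the (1 - p4)
weights rather than being dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SiteFrequencies",
    "QuartetResult",
    "site_abba_baba",
    "d_from_counts",
    "compute_d",
    "compute_f4",
    "f4_null_pvalue",
    "NullCalibration",
    "enumerate_quartets",
    "quartet_test",
    "dstat_table",
]


@dataclass
class SiteFrequencies:
    """Per-site derived (alt) allele frequencies for a species quartet.

    NaN marks missing; a site contributes only if all four frequencies are
    present.  Order is (P1, P2, P3, outgroup).
    """

    labels: tuple[str, str, str, str]
    p: np.ndarray  # (n_sites, 4) float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[1] != 4:
            raise ValueError("p must be (n_sites, 4)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.p, initial=0.0) < 0 or np.nanmax(self.p, initial=0.0) > 1:
                raise ValueError("frequencies must be in [0, 1]")

    @classmethod
    def from_table(cls, freq_table: pd.DataFrame, p1: str, p2: str, p3: str,
                   outgroup: str) -> "SiteFrequencies":
        return cls((p1, p2, p3, outgroup),
                   freq_table[[p1, p2, p3, outgroup]].to_numpy(dtype=float))

    def complete(self) -> np.ndarray:
        """Rows where all four frequencies are non-missing."""
        return self.p[np.isfinite(self.p).all(axis=1)]

    def polarized(self) -> np.ndarray:
        """Complete rows with alleles flipped so the outgroup allele is
        ancestral (derived frequency in the outgroup <= 0.5 per site)."""
        p = self.complete()
        flip = p[:, 3] > 0.5
        p = p.copy()
        p[flip] = 1.0 - p[flip]
        return p


@dataclass
class QuartetResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    n: int
    c_abba: float
    c_baba: float
    d: float
    f4: float
    p_value: float | None = None
    n_reps: int | None = None

    def to_row(self) -> dict:
        return {"P1": self.p1, "P2": self.p2, "P3": self.p3, "outgroup": self.outgroup,
                "n": self.n, "C_ABBA": self.c_abba, "C_BABA": self.c_baba,
                "D": self.d, "f4": self.f4, "p": self.p_value}


def site_abba_baba(p1, p2, p3, p4) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted ABBA and BABA weights (scalars or arrays)."""
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def d_from_counts(c_abba: float, c_baba: float) -> float:
    """D from pre-summed pattern counts; undefined (NaN) when both are 0."""
    tot = c_abba + c_baba
    if tot <= 0:
        return float("nan")
    return (c_abba - c_baba) / tot


def _variable_rows(p: np.ndarray) -> np.ndarray:
    return (p.max(axis=1) > 0) & (p.min(axis=1) < 1)


def compute_d(freqs: SiteFrequencies) -> QuartetResult:
    """Patterson's D with pattern weights summed over polarized sites.

    n counts the contributing sites variable among the four populations.
    D is NaN (flagged undefined) when no site carries ABBA or BABA weight.
    """
    p = freqs.polarized()
    if len(p) == 0:
        raise ValueError("no site has all four frequencies called")
    abba, baba = site_abba_baba(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
    c_abba, c_baba = float(abba.sum()), float(baba.sum())
    f4 = compute_f4(freqs)
    return QuartetResult(*freqs.labels, n=int(_variable_rows(p).sum()),
                         c_abba=c_abba, c_baba=c_baba,
                         d=d_from_counts(c_abba, c_baba), f4=f4)


def compute_f4(freqs: SiteFrequencies) -> float:
    """Mean over contributing sites of (p1 - p2) * (p3 - p4); invariant to
    joint allele relabeling, so polarization is immaterial."""
    p = freqs.complete()
    if len(p) == 0:
        raise ValueError("no site has all four frequencies called")
    return float(np.mean((p[:, 0] - p[:, 1]) * (p[:, 2] - p[:, 3])))


# ---------------------------------------------------------------------------
# Simulation null for f4
# ---------------------------------------------------------------------------

# Branch indexing of the no-admixture quartet model (((P1,P2),P3),O):
# 0..3 tip branches of P1, P2, P3, O; 4 the internal branch above (P1,P2);
# 5 the internal branch above (P1,P2,P3).  Branch drift is the
# Balding-Nichols fixation index F accumulated on that branch.
_PAIRS = [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3), (2, 3)]
_PATHS = {  # branches separating each pair
    (0, 1): (0, 1), (0, 2): (0, 4, 2), (1, 2): (1, 4, 2),
    (0, 3): (0, 4, 5, 3), (1, 3): (1, 4, 5, 3), (2, 3): (2, 5, 3),
}


@dataclass
class NullCalibration:
    drift: np.ndarray          # fitted per-branch F
    c0: float                  # fitted ancestral mean p(1-p)
    converged: bool
    dissim_observed: np.ndarray
    dissim_simulated: np.ndarray
    iterations: int


def _pair_dissimilarity(p: np.ndarray) -> np.ndarray:
    """Mean (p_i - p_j)^2 for the six population pairs."""
    return np.array([np.mean((p[:, i] - p[:, j]) ** 2) for i, j in _PAIRS])


def _bn(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Vectorized Balding-Nichols step (interior frequencies only drift)."""
    if f <= 0:
        return p
    f = min(f, 0.999)
    k = (1.0 - f) / f
    out = p.copy()
    interior = (p > 0) & (p < 1)
    pi = np.clip(p[interior], 1e-9, 1.0 - 1e-9)  # avoid underflow in beta params
    out[interior] = rng.beta(pi * k, (1.0 - pi) * k)
    return out


def _beta_shape(c0: float) -> float:
    """Shape a of the symmetric Beta(a, a) ancestral distribution with
    E p(1-p) = c0 = a / (2 (2a + 1))."""
    c0 = min(max(c0, 1e-6), 0.2499)
    return 2.0 * c0 / (1.0 - 4.0 * c0)


def _simulate_null(rng: np.random.Generator, c0: float, drift: np.ndarray,
                   shape: tuple[int, ...]) -> np.ndarray:
    """Simulate quartet frequencies under the fitted null; returns an array
    of shape ``shape + (4,)``.  Ancestral frequencies are Beta(a, a) with a
    matched to the fitted ancestral diversity c0."""
    a = _beta_shape(c0)
    q_anc = rng.beta(a, a, size=shape)
    q123 = _bn(rng, q_anc, drift[5])
    q12 = _bn(rng, q123, drift[4])
    sim = np.empty(shape + (4,))
    sim[..., 0] = _bn(rng, q12, drift[0])
    sim[..., 1] = _bn(rng, q12, drift[1])
    sim[..., 2] = _bn(rng, q123, drift[2])
    sim[..., 3] = _bn(rng, q_anc, drift[3])
    return sim


def _expected_dissim(u: np.ndarray, c0: float) -> np.ndarray:
    """Closed-form E(p_i - p_j)^2 for all pairs under Balding-Nichols drift:
    c0 (2 g_ij - g_i - g_j) with g the product of (1 - F) = exp(-u) from the
    root to a node and c0 the ancestral mean p(1-p)."""
    x = np.exp(-u)
    g = {0: x[5] * x[4] * x[0], 1: x[5] * x[4] * x[1], 2: x[5] * x[2], 3: x[3]}
    g_mrca = {(0, 1): x[5] * x[4], (0, 2): x[5], (1, 2): x[5],
              (0, 3): 1.0, (1, 3): 1.0, (2, 3): 1.0}
    return np.array([c0 * (2 * g_mrca[pr] - g[pr[0]] - g[pr[1]]) for pr in _PAIRS])


def _fit_drift_moments(d_obs: np.ndarray) -> tuple[np.ndarray, float]:
    """Moment-match per-branch drift and ancestral diversity to the observed
    pair dissimilarities.

    Drift products are additive in u = -log(1 - F), so the six pair
    equations are solved for the six branch u plus the ancestral c0 by
    bounded least squares.  Returns (per-branch F, c0)."""
    scale = np.maximum(d_obs, 1e-8)

    def resid(theta: np.ndarray) -> np.ndarray:
        return (_expected_dissim(theta[:6], theta[6]) - d_obs) / scale

    c0_init = min(max(0.6 * float(d_obs.max()), 0.01), 0.24)
    x0 = np.concatenate([np.full(6, 0.05), [c0_init]])
    fit = least_squares(resid, x0=x0, bounds=([0.0] * 6 + [1e-4], [8.0] * 6 + [0.2499]),
                        xtol=1e-12)
    return 1.0 - np.exp(-fit.x[:6]), float(fit.x[6])


def f4_null_pvalue(freqs: SiteFrequencies, n_reps: int = 400, seed: int = 0,
                   rel_tol: float = 0.10, max_adjust: int = 30,
                   burnin_sites: int = 4000) -> tuple[float | None, NullCalibration]:
    """One-sided simulation p-value for f4 against a no-admixture null.

    Burnin: per-branch drift of the quartet model is first moment-matched
    to the observed pairwise allele-frequency dissimilarities, then
    iteratively adjusted on simulated datasets until every pair matches
    within ``rel_tol`` (relative).  Main phase: ``n_reps`` datasets of the
    observed size are simulated and p is the fraction with f4 at least as
    extreme as observed, one-sided in the sign of the observed f4 (an
    observed f4 of exactly 0 is maximally unextreme, p = 1).  Returns
    (p or None if burnin failed, calibration diagnostics).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    p_obs = freqs.complete()
    if len(p_obs) == 0:
        raise ValueError("no site has all four frequencies called")
    f4_obs = compute_f4(freqs)
    rng = np.random.default_rng(seed)
    d_obs = _pair_dissimilarity(p_obs)
    drift, c0 = _fit_drift_moments(d_obs)

    d_sim = d_obs.copy()
    converged = False
    it = 0
    for it in range(1, max_adjust + 1):
        sim = _simulate_null(rng, c0, drift, (burnin_sites,))
        d_sim = _pair_dissimilarity(sim)
        ratio = np.where(d_sim > 0, d_obs / np.maximum(d_sim, 1e-12), 1.0)
        atol = 1e-6  # pairs with essentially no observed dissimilarity always match
        if np.all(np.abs(d_sim - d_obs) <= np.maximum(rel_tol * d_obs, atol)):
            converged = True
            break
        # damped multiplicative update of each branch's u = -log(1-F)
        u = -np.log(np.maximum(1.0 - drift, 1e-12))
        for b in range(6):
            rs = [ratio[k] for k, pr in enumerate(_PAIRS) if b in _PATHS[pr]]
            u[b] = np.clip(u[b] * float(np.exp(0.5 * np.mean(np.log(np.maximum(rs, 1e-6))))),
                           0.0, 8.0)
        drift = 1.0 - np.exp(-u)
    cal = NullCalibration(drift, c0, converged, d_obs, d_sim, it)
    if not converged:
        return None, cal

    n_sites = len(p_obs)
    hits = 0
    block = max(1, int(2e6 // max(n_sites, 1)))
    done = 0
    f4_null = np.empty(n_reps)
    while done < n_reps:
        b = min(block, n_reps - done)
        sim = _simulate_null(rng, c0, drift, (b, n_sites))
        f4_null[done:done + b] = np.mean((sim[..., 0] - sim[..., 1])
                                         * (sim[..., 2] - sim[..., 3]), axis=1)
        done += b
    if f4_obs == 0:
        p_val = 1.0
    elif f4_obs > 0:
        p_val = float(np.mean(f4_null >= f4_obs))
    else:
        p_val = float(np.mean(f4_null <= f4_obs))
    return p_val, cal


# ---------------------------------------------------------------------------
# Quartet enumeration and tables
# ---------------------------------------------------------------------------


def enumerate_quartets(tree, outgroups=None) -> list[tuple[str, str, str, str]]:
    """All (P1, P2, P3, outgroup) quartets compatible with a rooted species
    tree: P1 and P2 are sisters relative to P3, and the outgroup is outgroup
    to all three.  The P1/P2 orientation is canonical (alphabetical); the
    data-driven positive-D orientation is chosen in :func:`dstat_table`.
    ``outgroups`` optionally restricts the outgroup position.
    """
    tips = tree.tips()
    if len(tips) < 4:
        return []
    out_choices = sorted(outgroups) if outgroups is not None else tips
    quartets = []
    for a, b, c in itertools.combinations(tips, 3):
        # find the sister pair among {a, b, c}
        pairs = [(a, b, c), (a, c, b), (b, c, a)]
        sister = None
        for x, y, z in pairs:
            if tree.mrca_age([x, y]) < tree.mrca_age([x, z]) and \
               tree.mrca_age([x, y]) < tree.mrca_age([y, z]):
                sister = (x, y, z)
        if sister is None:
            continue  # unresolved trio
        x, y, z = sister
        trio_age = tree.mrca_age([x, y, z])
        for o in out_choices:
            if o in (x, y, z):
                continue
            if tree.mrca_age([x, y, z, o]) > trio_age:
                quartets.append((min(x, y), max(x, y), z, o))
    return sorted(set(quartets))


def quartet_test(freq_table: pd.DataFrame, p1: str, p2: str, p3: str, outgroup: str,
                 n_reps: int = 400, seed: int = 0) -> QuartetResult:
    """D, f4, and the simulation p-value for one quartet orientation."""
    freqs = SiteFrequencies.from_table(freq_table, p1, p2, p3, outgroup)
    res = compute_d(freqs)
    if n_reps:
        p_val, _ = f4_null_pvalue(freqs, n_reps=n_reps, seed=seed)
        res.p_value = p_val
        res.n_reps = n_reps
    return res


def dstat_table(freq_table: pd.DataFrame, tree, outgroups=None, n_reps: int = 0,
                seed: int = 0, fdr: bool = False) -> pd.DataFrame:
    """Quartet scan over all tree-compatible quartets.

    Each quartet is run once per candidate outgroup; P1/P2 are oriented so
    that D >= 0 and, when several outgroups apply, the run with the largest
    D is flagged ``reported`` (all runs are retained).  ``n_reps`` > 0 adds
    simulation p-values; ``fdr`` adds a Benjamini-Hochberg column (off by
    default: the quartet tests are reported unadjusted).
    """
    rows = []
    for k, (p1, p2, p3, o) in enumerate(enumerate_quartets(tree, outgroups)):
        res = quartet_test(freq_table, p1, p2, p3, o, n_reps=n_reps,
                           seed=seed + k if n_reps else 0)
        if np.isfinite(res.d) and res.d < 0:
            res = quartet_test(freq_table, p2, p1, p3, o, n_reps=n_reps,
                               seed=seed + k if n_reps else 0)
        rows.append(res.to_row())
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["reported"] = False
    key = df.apply(lambda r: (tuple(sorted((r["P1"], r["P2"]))), r["P3"]), axis=1)
    for _, grp in df.groupby(key, sort=False):
        df.loc[grp["D"].idxmax(), "reported"] = True
    if fdr and "p" in df and df["p"].notna().any():
        from statsmodels.stats.multitest import multipletests

        mask = df["p"].notna()
        df.loc[mask, "p_bh"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df
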