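"""Morphometrics: derived measures, ratio PCA, and maternal similarity.

From the raw measurements — total length TL, preanal length PA, predorsal
length PD, and head length HL — the derived measures are

    AD  = PA - PD   (anus to dorsal-fin distance)
    PDH = PD - HL   (predorsal length without head)
    T   = TL - PA   (tail length)
    TR  = PA - HL   (preanal length without head)

and the seven analysis traits are the ratios of PA, T, HL, TR, PD, PDH, AD
to TL.  The maternal-similarity statistic places a hybrid's (PDH/TL, AD/TL)
phenotype on the axis between the parental species means:

    f_m,morphology = 1 - 1/2 * [ (PDH/TL - m_PDH) / (p_PDH - m_PDH)
                               + (AD/TL  - m_AD)  / (p_AD  - m_AD) ]

with m/p the maternal/paternal species means.  Values outside [0, 1]
indicate transgressive phenotypes and are deliberately not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RATIO_TRAITS",
    "SpeciesMorphSummary",
    "derive_measures",
    "morpho_pca",
    "species_morph_summary",
    "f_m_morphology",
    "genome_morph_association",
]

RAW_REQUIRED = ["TL", "PA", "PD", "HL"]
RATIO_TRAITS = ["PA_TL", "T_TL", "HL_TL", "TR_TL", "PD_TL", "PDH_TL", "AD_TL"]


@dataclass(frozen=True)
class SpeciesMorphSummary:
    """Per-species mean (PDH/TL, AD/TL), with the sample count behind it."""

    species: str
    mean_pdh_tl: float
    mean_ad_tl: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary requires at least one record")
        if not (np.isfinite(self.mean_pdh_tl) and np.isfinite(self.mean_ad_tl)):
            raise ValueError("non-finite species means")


def derive_measures(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute derived measures and ratio traits from raw measurements.

    Returns (records, rejected): rows missing a required field or with
    non-positive TL are excluded from ``records`` and listed in ``rejected``
    with a reason column.
    """
    missing_cols = [c for c in RAW_REQUIRED if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"raw table lacks columns {missing_cols}")
    df = raw.copy()
    reasons = pd.Series("", index=df.index, dtype=object)
    incomplete = df[RAW_REQUIRED].isna().any(axis=1)
    reasons[incomplete] = "missing required measurement"
    nonpos = ~incomplete & (df["TL"] <= 0)
    reasons[nonpos] = "non-positive TL"
    rejected = df[reasons != ""].assign(reason=reasons[reasons != ""])
    df = df[reasons == ""].copy()

    df["AD"] = df["PA"] - df["PD"]
    df["PDH"] = df["PD"] - df["HL"]
    df["T"] = df["TL"] - df["PA"]
    df["TR"] = df["PA"] - df["HL"]
    for num, name in [("PA", "PA_TL"), ("T", "T_TL"), ("HL", "HL_TL"), ("TR", "TR_TL"),
                      ("PD", "PD_TL"), ("PDH", "PDH_TL"), ("AD", "AD_TL")]:
        df[name] = df[num] / df["TL"]
    band = df[RATIO_TRAITS].abs().ge(1.0).any(axis=1)
    if band.any():
        rejected = pd.concat([rejected, df[band].assign(reason="ratio outside sanity band")])
        df = df[~band]
    return df, rejected


def morpho_pca(records: pd.DataFrame, traits: list[str] = RATIO_TRAITS,
               standardize: bool = True) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the ratio traits (standardized by default, since the ratios
    have unequal variances).  Returns (scores, loadings, explained-variance
    ratios); rank-deficient input simply yields fewer components.  Score
    signs are arbitrary up to a global flip per component.
    """
    data = records[traits].dropna()
    if len(data) < 3:
        raise ValueError("PCA requires at least 3 complete records")
    from sklearn.decomposition import PCA

    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    rank = int(np.linalg.matrix_rank(x))
    pca = PCA(n_components=min(rank, len(traits), len(data) - 1))
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=data.index, columns=cols),
            pd.DataFrame(pca.components_.T, index=traits, columns=cols),
            pca.explained_variance_ratio_)


def species_morph_summary(records: pd.DataFrame, species: str,
                          meta: pd.DataFrame | None = None,
                          core_only: bool = True) -> SpeciesMorphSummary:
    """Mean (PDH/TL, AD/TL) for one species.

    If ``meta`` is given, membership comes from its species column
    (restricted to core-group individuals when ``core_only``); otherwise
    ``records`` must carry a species column.
    """
    if meta is not None:
        rows = meta[meta["species"] == species]
        if core_only and "core_group" in meta.columns:
            rows = rows[rows["core_group"].astype(bool)]
        sub = records[records["sample_id"].isin(rows["sample_id"])]
    else:
        sub = records[records["species"] == species]
    sub = sub.dropna(subset=["PDH_TL", "AD_TL"])
    if sub.empty:
        raise ValueError(f"no usable morphology records for species {species!r}")
    return SpeciesMorphSummary(species, float(sub["PDH_TL"].mean()),
                               float(sub["AD_TL"].mean()), len(sub))


def f_m_morphology(hybrid, maternal: SpeciesMorphSummary,
                   paternal: SpeciesMorphSummary) -> float:
    """Relative morphological similarity of a hybrid to its maternal species.

    ``hybrid`` is a record (mapping or Series) with PDH_TL and AD_TL.
    Equals 1 at the maternal means, 0 at the paternal means, 0.5 at the
    midpoint; transgressive phenotypes fall outside [0, 1] and are not
    clamped.  Raises if the parental means coincide in either trait.
    """
    d_pdh = paternal.mean_pdh_tl - maternal.mean_pdh_tl
    d_ad = paternal.mean_ad_tl - maternal.mean_ad_tl
    if d_pdh == 0:
        raise ZeroDivisionError("parental means equal in PDH/TL; similarity undefined")
    if d_ad == 0:
        raise ZeroDivisionError("parental means equal in AD/TL; similarity undefined")
    term_pdh = (hybrid["PDH_TL"] - maternal.mean_pdh_tl) / d_pdh
    term_ad = (hybrid["AD_TL"] - maternal.mean_ad_tl) / d_ad
    return float(1.0 - 0.5 * (term_pdh + term_ad))


def genome_morph_association(pairs) -> dict:
    """OLS of f_m,morphology on f_m,genome with a two-tailed t test.

    ``pairs`` is a sequence of (f_m_genome, f_m_morphology) or a DataFrame
    with those columns.  Returns slope, intercept, t, p (two-tailed), and
    R^2.  Requires at least 3 pairs and a non-degenerate predictor.
    """
    if isinstance(pairs, pd.DataFrame):
        x = pairs["f_m_genome"].to_numpy(dtype=float)
        y = pairs["f_m_morphology"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in f_m,genome; association undefined")
    fit = stats.linregress(x, y)
    with np.errstate(divide="ignore"):
        t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
    return {"slope": fit.slope, "intercept": fit.intercept, "t": float(t),
            "p": fit.pvalue, "r_squared": fit.rvalue ** 2, "n": len(x)}
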