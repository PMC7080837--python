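"""Sliding-window topology classification along chromosome alignments.

For a 4-taxon whole-scaffold alignment, each window (default 20 kb,
stepped by 10 kb, 0-based half-open internally) is fit under the three
resolved quartet topologies with the genealogy-interrogation likelihood
engine; the best-scoring topology is reported, windows with too few usable
variable sites or with tied likelihoods are "undetermined".  Long runs of
adjacent windows supporting the same alternative topology are the signature
of recent hybrid ancestry, so the summary reports the longest contiguous
alternative-topology span in bp (first window start to last window end of
the run, overlapping windows included).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genealogy_interrogation import LocusAlignment, fit_constrained

__all__ = ["WindowTopologyRecord", "window_scan", "summarize_blocks", "records_to_frame",
           "write_bed"]

UNDETERMINED = "undetermined"


@dataclass
class WindowTopologyRecord:
    scaffold: str
    start: int  # 0-based, half-open
    end: int
    topology: str  # sister-pair label "a+b", or "undetermined"
    lnl: dict[str, float]
    n_sites: int


def _quartet_topologies(taxa: list[str], outgroup: str) -> dict[str, str]:
    """The three resolved rooted quartet topologies, labeled by the ingroup
    sister pair they place together."""
    ingroup = [t for t in taxa if t != outgroup]
    if len(ingroup) != 3:
        raise ValueError("window scan requires exactly 4 taxa including the outgroup")
    out = {}
    for a, b in itertools.combinations(sorted(ingroup), 2):
        c = next(t for t in ingroup if t not in (a, b))
        out[f"{a}+{b}"] = f"((({a},{b}),{c}),{outgroup});"
    return out


def window_scan(aln: LocusAlignment, outgroup: str, window: int = 20_000,
                step: int = 10_000, min_sites: int = 10,
                subst_model: str = "JC", tie_tol: float = 0.01) -> list[WindowTopologyRecord]:
    """Classify the supported quartet topology in sliding windows.

    A window's usable sites are columns with all four taxa called; it must
    contain at least ``min_sites`` usable *variable* sites to be classified.
    A scaffold shorter than one window yields a single terminal window.
    """
    if len(aln.taxa) != 4:
        raise ValueError("alignment must contain exactly 4 sequences")
    if outgroup not in aln.taxa:
        raise KeyError(f"outgroup {outgroup!r} not in alignment")
    topologies = _quartet_topologies(aln.taxa, outgroup)
    records = []
    length = aln.length
    starts = range(0, max(length - window, 0) + 1, step) if length >= window else [0]
    for start in starts:
        end = min(start + window, length)
        sub = aln.window(start, end)
        codes = sub.codes
        complete = (codes >= 0).all(axis=0)
        var = complete & (codes.max(axis=0) != np.where(complete, codes.min(axis=0), 0))
        n_var = int(var.sum())
        lnls: dict[str, float] = {}
        if n_var < min_sites:
            call = UNDETERMINED
        else:
            for label, nwk in topologies.items():
                lnls[label] = fit_constrained(sub, nwk, subst_model=subst_model).lnl
            ordered = sorted(lnls.items(), key=lambda kv: -kv[1])
            call = ordered[0][0] if ordered[0][1] - ordered[1][1] > tie_tol else UNDETERMINED
        records.append(WindowTopologyRecord(aln.locus_id, start, end, call, lnls, n_var))
    return records


def summarize_blocks(records, species_topology: str | None = None) -> dict:
    """Counts/percentages per topology and the longest alternative run.

    ``species_topology`` names the sister-pair label of the species tree;
    if omitted, the most frequent resolved call is taken as the species
    topology.  The longest run is the genomic span (bp) from the first
    window start to the last window end of a maximal run of consecutive
    windows with the same alternative topology on one scaffold.
    """
    records = sorted(records, key=lambda r: (r.scaffold, r.start))
    calls = [r.topology for r in records]
    counts = pd.Series(calls).value_counts().to_dict()
    resolved = {k: v for k, v in counts.items() if k != UNDETERMINED}
    total_resolved = sum(resolved.values())
    if species_topology is None:
        species_topology = max(resolved, key=resolved.get) if resolved else None
    longest = 0
    longest_run: tuple[str, int, int] | None = None
    for (scaffold, topo), group in itertools.groupby(
            records, key=lambda r: (r.scaffold, r.topology)):
        if topo in (UNDETERMINED, species_topology):
            continue
        group = list(group)
        span = group[-1].end - group[0].start
        if span > longest:
            longest = span
            longest_run = (scaffold, group[0].start, group[-1].end)
    return {
        "counts": counts,
        "percent_of_resolved": {k: 100.0 * v / total_resolved for k, v in resolved.items()}
        if total_resolved else {},
        "species_topology": species_topology,
        "longest_alternative_span_bp": longest,
        "longest_alternative_run": longest_run,
        "n_windows": len(records),
    }


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"scaffold": r.scaffold, "start": r.start, "end": r.end,
               "topology": r.topology, "n_sites": r.n_sites}
        for k, v in r.lnl.items():
            row[f"lnl_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_bed(records, path) -> None:
    """Window calls as BED (0-based half-open, name = topology call)."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.scaffold, r.start)):
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.topology}\n")
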