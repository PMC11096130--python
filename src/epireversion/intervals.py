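"""Interval algebra on genomic coordinates.

Implements the consolidation and classification rules applied to peak and
domain calls: confident-peak consolidation across replicates, gap-aware
domain stitching, Polycomb-target classification by gene-body overlap,
activating-mark gene hits, and nearest-TSS peak assignment.

All coordinates are 0-based half-open.  Interval collections are plain
pandas DataFrames with at least ``chrom``/``start``/``end`` columns; domain
sets are kept sorted and non-overlapping.  Data volumes here are small
(thousands of intervals), so the implementations favour clarity and exact
agreement with per-base brute-force oracles over asymptotics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "merge_intervals",
    "consolidate_peaks",
    "stitch_domains",
    "classify_pcg_targets",
    "gene_has_active_peak",
    "assign_peaks_to_tss",
]

# Merge-gap thresholds: adjacent retained peaks closer than these are fused.
NARROW_GAP = 250      # PH / H3K27Ac / ATAC peaks
BROAD_GAP = 2500      # H3K27me3 / H2AK118Ub domains


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Fuse intervals whose separation (next.start - prev.end) is <= ``gap``.

    ``gap=0`` unions overlapping or touching intervals.  Output is sorted
    and non-overlapping, per chromosome.
    """
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _overlaps_any(chrom, start, end, other: pd.DataFrame) -> bool:
    sub = other[other["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def consolidate_peaks(rep1: pd.DataFrame, rep2: pd.DataFrame, merged: pd.DataFrame,
                      mode: str = "narrow") -> pd.DataFrame:
    """Retain reproducible, confidently called peaks and fuse nearby survivors.

    A merged-replicate call is kept when it passes the stringent merged
    thresholds (enrichment > 2 AND q < 0.01) and overlaps, by at least 1 bp,
    a passing call (enrichment > 0 AND q < 0.05) in *both* replicates.
    Retained intervals are then fused with a gap threshold of 250 bp for
    narrow peaks or 2,500 bp for broad marks.
    """
    if mode == "narrow":
        gap = NARROW_GAP
    elif mode == "broad":
        gap = BROAD_GAP
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'narrow' or 'broad'")

    r1 = rep1[(rep1["enrichment"] > 0) & (rep1["qvalue"] < 0.05)]
    r2 = rep2[(rep2["enrichment"] > 0) & (rep2["qvalue"] < 0.05)]
    cand = merged[(merged["enrichment"] > 2) & (merged["qvalue"] < 0.01)]

    keep = [
        _overlaps_any(row.chrom, row.start, row.end, r1)
        and _overlaps_any(row.chrom, row.start, row.end, r2)
        for row in cand.itertuples()
    ]
    retained = cand[np.asarray(keep, dtype=bool)] if len(cand) else cand
    return merge_intervals(retained[["chrom", "start", "end"]], gap=gap)


def stitch_domains(domains: pd.DataFrame, assembly_gaps: pd.DataFrame | None) -> pd.DataFrame:
    """Fuse adjacent domains split by assembly gaps.

    Two consecutive domains on a chromosome are fused iff the region between
    them is entirely covered by the union of assembly-gap intervals.  With no
    gap set, the (merged) input is returned unchanged.
    """
    domains = merge_intervals(domains, gap=0)
    if assembly_gaps is None or len(assembly_gaps) == 0:
        return domains
    gaps = merge_intervals(assembly_gaps, gap=0)
    out = []
    for chrom, sub in domains.groupby("chrom", sort=True):
        gsub = gaps[gaps["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            between = gsub[(gsub["start"] <= cur_e) & (gsub["end"] >= s)]
            covered = bool(((between["start"] <= cur_e) & (between["end"] >= s)).any())
            if covered:
                cur_e = int(e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _overlap_bp(start, end, other_starts, other_ends) -> int:
    lo = np.maximum(start, other_starts)
    hi = np.minimum(end, other_ends)
    return int(np.clip(hi - lo, 0, None).sum())


def classify_pcg_targets(genes: pd.DataFrame, domains: pd.DataFrame,
                         min_fraction: float = 0.5) -> pd.DataFrame:
    """Flag genes whose body is covered >= ``min_fraction`` by repressive domains.

    ``domains`` must be non-overlapping (use :func:`merge_intervals` first);
    the boundary is inclusive: exactly 50% coverage is a target.
    Returns a frame with gene_id, overlap_fraction and pcg_target.
    """
    if (genes["start"] >= genes["end"]).any():
        bad = genes.loc[genes["start"] >= genes["end"], "gene_id"].iloc[0]
        raise ValueError(f"zero-length gene body for {bad!r}")
    rows = []
    by_chrom = {c: sub for c, sub in domains.groupby("chrom")}
    for g in genes.itertuples():
        sub = by_chrom.get(g.chrom)
        if sub is None:
            frac = 0.0
        else:
            bp = _overlap_bp(g.start, g.end, sub["start"].to_numpy(), sub["end"].to_numpy())
            frac = bp / (g.end - g.start)
        rows.append((g.gene_id, frac, frac >= min_fraction))
    return pd.DataFrame(rows, columns=["gene_id", "overlap_fraction", "pcg_target"])


def gene_has_active_peak(genes: pd.DataFrame, peaks: pd.DataFrame,
                         upstream: int = 2500) -> pd.Series:
    """True when a peak overlaps a gene body or its strand-aware upstream window.

    The window extends ``upstream`` bp 5' of the TSS: left of ``start`` on
    "+" genes, right of ``end`` on "-" genes, clipped at position 0.
    """
    flags = []
    by_chrom = {c: sub for c, sub in peaks.groupby("chrom")}
    for g in genes.itertuples():
        if g.strand == "+":
            lo, hi = max(0, g.start - upstream), g.end
        else:
            lo, hi = g.start, g.end + upstream
        sub = by_chrom.get(g.chrom)
        hit = False
        if sub is not None:
            hit = bool(((sub["start"] < hi) & (sub["end"] > lo)).any())
        flags.append(hit)
    return pd.Series(flags, index=genes["gene_id"].to_numpy(), name="active_peak")


def assign_peaks_to_tss(peaks: pd.DataFrame, genes: pd.DataFrame,
                        max_sep: int = 25_000, distal_cutoff: int = 1_000) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS within ``max_sep`` bp.

    The peak anchor is its midpoint (floor of (start+end)/2).  Distance is
    signed (tss - midpoint); assignment compares absolute distances, with
    ties broken by the lexicographically smaller gene_id.  Peaks farther
    than ``max_sep`` from every TSS are left unassigned.  ``tss_distal``
    flags assigned peaks more than ``distal_cutoff`` bp from their TSS.
    """
    rows = []
    gene_by_chrom = {
        c: sub.sort_values(["tss", "gene_id"]) for c, sub in genes.groupby("chrom")
    }
    for p in peaks.itertuples():
        name = getattr(p, "name", f"{p.chrom}:{p.start}-{p.end}")
        mid = (p.start + p.end) // 2
        sub = gene_by_chrom.get(p.chrom)
        if sub is None or len(sub) == 0:
            rows.append((name, None, np.nan, None))
            continue
        dist = sub["tss"].to_numpy() - mid
        order = np.lexsort((sub["gene_id"].to_numpy(), np.abs(dist)))
        best = order[0]
        if abs(int(dist[best])) > max_sep:
            rows.append((name, None, np.nan, None))
        else:
            d = int(dist[best])
            rows.append((name, sub["gene_id"].iloc[best], d, abs(d) > distal_cutoff))
    return pd.DataFrame(rows, columns=["peak", "gene_id", "distance", "tss_distal"])
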