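"""H3K27me3 analysis: input-normalized ratio tracks, gene marking, concordance.

A gene counts as H3K27me3-marked when strictly more than half of its
transcribed region (annotated body) overlaps the union of enrichment
peaks.  Coverage ratios are computed after scaling each library to
counts per million, so doubling one library's depth leaves the ratio
unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracks import BinTrack


def coverage_ratio_track(
    k27: BinTrack,
    h3: BinTrack,
    pseudocount: float = 0.0,
    scaling: str = "cpm",
) -> BinTrack:
    """Per-window ratio of normalized H3K27me3 over H3 coverage.

    Both tracks are scaled to counts per million of their own totals
    (or to unit genome-wide mean with ``scaling="mean"``); the ratio is
    undefined where the scaled H3 signal (plus pseudocount) is zero.
    """
    if not k27.same_bins(h3):
        raise ValueError("coverage tracks are on different windows")
    tot_k, tot_h = np.nansum(k27.values), np.nansum(h3.values)
    if tot_k <= 0 or tot_h <= 0:
        raise ValueError("zero total coverage in one of the tracks")
    if scaling == "cpm":
        k = k27.values / tot_k * 1e6
        h = h3.values / tot_h * 1e6
    elif scaling == "mean":
        k = k27.values / np.nanmean(k27.values)
        h = h3.values / np.nanmean(h3.values)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    denom = h + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, (k + pseudocount) / denom, np.nan)
    return BinTrack(
        k27.bins.copy(), ratio, k27.resolution, name="k27_h3_ratio"
    )


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping intervals, per chromosome."""
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=False):
        g = grp.sort_values("start", kind="stable")
        cur_s = cur_e = None
        for s, e in zip(g["start"], g["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _overlap_length(
    start: int, end: int, merged_starts: np.ndarray, merged_ends: np.ndarray
) -> int:
    lo = np.searchsorted(merged_ends, start, side="right")
    hi = np.searchsorted(merged_starts, end, side="left")
    if hi <= lo:
        return 0
    s = np.maximum(merged_starts[lo:hi], start)
    e = np.minimum(merged_ends[lo:hi], end)
    return int(np.sum(np.maximum(e - s, 0)))


def mark_genes_by_peaks(
    genes: pd.DataFrame, peaks: pd.DataFrame, min_fraction: float = 0.5
) -> set[str]:
    """Genes whose body overlap with the peak union exceeds ``min_fraction``.

    Strict inequality: a gene exactly half covered is NOT marked.
    """
    merged = merge_intervals(peaks) if len(peaks) else peaks
    by_chrom = {}
    if len(merged):
        for chrom, grp in merged.groupby("chrom", sort=False):
            g = grp.sort_values("start", kind="stable")
            by_chrom[chrom] = (
                g["start"].to_numpy(),
                g["end"].to_numpy(),
            )
    marked = set()
    for _, g in genes.iterrows():
        length = g["end"] - g["start"]
        if length < 0:
            raise ValueError(f"gene {g.get('gene_id', '?')!r} has negative length")
        if length == 0 or g["chrom"] not in by_chrom:
            continue
        ms, me = by_chrom[g["chrom"]]
        ov = _overlap_length(g["start"], g["end"], ms, me)
        if ov > min_fraction * length:
            marked.add(g["gene_id"])
    return marked


def marked_set_concordance(
    set_parent: set, set_hybrid: set, universe: set
) -> dict:
    """Partition of the gene universe by parent/hybrid mark status."""
    if not set_parent <= universe or not set_hybrid <= universe:
        raise ValueError("marked sets must be subsets of the universe")
    both = set_parent & set_hybrid
    parent_only = set_parent - set_hybrid
    hybrid_only = set_hybrid - set_parent
    neither = universe - set_parent - set_hybrid
    out = {
        "both": len(both),
        "parent_only": len(parent_only),
        "hybrid_only": len(hybrid_only),
        "neither": len(neither),
        "shared_of_parent": (
            len(both) / len(set_parent) if set_parent else None
        ),
        "shared_of_universe": len(both) / len(universe) if universe else None,
    }
    return out


def call_peaks_simple(
    ratio: BinTrack, threshold: float, merge_gap_windows: int = 2
) -> pd.DataFrame:
    """Threshold-and-merge peak caller — plumbing for synthetic tracks only.

    Windows with ratio > threshold become peaks; runs separated by fewer
    than ``merge_gap_windows`` sub-threshold windows are merged.  This
    is not a statistical peak caller.
    """
    rows = []
    for chrom in dict.fromkeys(ratio.bins["chrom"]):
        sel = ratio.chrom_slice(chrom)
        vals = ratio.values[sel]
        starts = ratio.bins["start"].to_numpy()[sel]
        ends = ratio.bins["end"].to_numpy()[sel]
        above = np.flatnonzero(~np.isnan(vals) & (vals > threshold))
        if above.size == 0:
            continue
        run_s = above[0]
        prev = above[0]
        for idx in above[1:]:
            if idx - prev > merge_gap_windows:
                rows.append((chrom, starts[run_s], ends[prev]))
                run_s = idx
            prev = idx
        rows.append((chrom, starts[run_s], ends[prev]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def signal_by_compactness_rank(
    compactness, signal: BinTrack, n_ranks: int
) -> pd.DataFrame:
    """Mean signal per compactness rank group, weakest to strongest.

    Bins defined in both tracks are sorted ascending by compactness
    (stable, so coordinate order breaks ties) and partitioned into
    ``n_ranks`` groups; when the count is not divisible, the remainder
    is spread one extra bin per group from the low end.
    """
    ctrack = compactness.track if hasattr(compactness, "track") else compactness
    if not ctrack.same_bins(signal):
        raise ValueError("tracks are on different bins")
    ok = np.flatnonzero(ctrack.defined & signal.defined)
    if ok.size < n_ranks:
        raise ValueError("fewer defined bins than rank groups")
    order = ok[np.argsort(ctrack.values[ok], kind="stable")]
    base, rem = divmod(order.size, n_ranks)
    rows = []
    pos = 0
    for rank in range(n_ranks):
        size = base + (1 if rank < rem else 0)
        grp = order[pos : pos + size]
        pos += size
        rows.append(
            {
                "rank": rank + 1,
                "n": size,
                "mean_signal": float(np.mean(signal.values[grp])),
                "mean_compactness": float(np.mean(ctrack.values[grp])),
            }
        )
    return pd.DataFrame(rows)
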