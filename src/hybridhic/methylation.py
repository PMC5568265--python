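"""Bisulfite methylation-ratio tracks, cutoff grouping, metagene profiles.

The methylation ratio of a region is the pooled count ratio: total
methylated cytosines over total sequenced cytosines of the requested
context, never the mean of per-site ratios.  Pooling makes ratios over
a union of intervals equal the count-weighted combination of the
per-interval ratios, which windowed and whole-chromosome views rely on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .tracks import BinTrack, tile_genome

CONTEXTS = ("CG", "CHG", "CHH")


def _check_context(context: str) -> None:
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")


def _interval_sums(
    calls: pd.DataFrame, intervals: pd.DataFrame, context: str
) -> tuple[np.ndarray, np.ndarray]:
    """Σ methylated and Σ total per interval (intervals non-overlapping)."""
    meth = np.zeros(len(intervals))
    tot = np.zeros(len(intervals))
    sub = calls[calls["context"] == context]
    for chrom, grp in sub.groupby("chrom", sort=False):
        sel = np.flatnonzero((intervals["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        starts = intervals["start"].to_numpy()[sel]
        ends = intervals["end"].to_numpy()[sel]
        order = np.argsort(starts, kind="stable")
        starts_s, ends_s = starts[order], ends[order]
        pos = grp["pos"].to_numpy()
        idx = np.searchsorted(starts_s, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends_s[np.clip(idx, 0, None)])
        idx = idx[ok]
        np.add.at(meth, sel[order][idx], grp["methylated"].to_numpy()[ok])
        np.add.at(tot, sel[order][idx], grp["total"].to_numpy()[ok])
    return meth, tot


def methylation_ratio(
    calls: pd.DataFrame, intervals: pd.DataFrame, context: str
) -> BinTrack:
    """Pooled methylation ratio per interval; NaN where no covered sites."""
    _check_context(context)
    widths = intervals["end"].to_numpy() - intervals["start"].to_numpy()
    meth, tot = _interval_sums(calls, intervals, context)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tot > 0, meth / np.where(tot > 0, tot, 1), np.nan)
    res = int(widths[0]) if len(widths) else 0
    return BinTrack(
        intervals.reset_index(drop=True)[["chrom", "start", "end"]],
        ratio,
        res,
        name=f"m{context}",
    )


def chromosome_profile(
    calls: pd.DataFrame,
    context: str,
    bin: int = 50_000,
    layout: GenomeLayout | None = None,
) -> BinTrack:
    """Genome-tiling methylation ratio at ``bin`` resolution (default 50 kb).

    Bins fully inside layout segments labelled ``masked`` are forced
    undefined regardless of coverage.
    """
    _check_context(context)
    if bin <= 0:
        raise ValueError("bin size must be positive")
    if layout is not None:
        lengths = {c: layout.length(c) for c in layout.chrom_names}
    else:
        lengths = {
            c: int(grp["pos"].max()) + 1
            for c, grp in calls.groupby("chrom", sort=False)
        }
    bins = tile_genome(lengths, bin)
    track = methylation_ratio(calls, bins, context)
    if layout is not None:
        for _, seg in layout.masked_intervals().iterrows():
            inside = (
                (bins["chrom"] == seg["chrom"])
                & (bins["start"] >= seg["start"])
                & (bins["end"] <= seg["end"])
            ).to_numpy()
            track.values[inside] = np.nan
    track.resolution = bin
    return track


def split_bins_by_cutoff(
    track: BinTrack, cutoff: float, te_density: BinTrack
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Split defined bins at a cutoff and summarise TE fractions per group.

    Group 1 (low) collects bins with value <= cutoff, group 2 (high)
    those above; a value exactly at the cutoff goes to group 1.  Returns
    the two bin-index arrays and a per-group TE-fraction summary.
    """
    if not track.same_bins(te_density):
        raise ValueError("track and TE-density track are on different bins")
    defined = np.flatnonzero(track.defined)
    if defined.size == 0:
        raise ValueError("no defined bins to split")
    vals = track.values[defined]
    group1 = defined[vals <= cutoff]
    group2 = defined[vals > cutoff]
    rows = []
    for name, idx in (("group1", group1), ("group2", group2)):
        te = te_density.values[idx]
        te = te[~np.isnan(te)]
        rows.append(
            {
                "group": name,
                "n": int(idx.size),
                "te_mean": float(np.mean(te)) if te.size else np.nan,
                "te_median": float(np.median(te)) if te.size else np.nan,
            }
        )
    return group1, group2, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def metagene_profile(
    track_or_calls,
    genes: pd.DataFrame,
    body_bins: int = 60,
    flank_bp: int = 1_000,
    window: int = 100,
    context: str = "CHH",
    layout: GenomeLayout | None = None,
) -> np.ndarray:
    """Strand-aware TSS->TTS averaged profile.

    Each gene body is linearly rescaled to ``body_bins`` positions;
    flanks are absolute ``window``-bp steps (``flank_bp // window`` on
    each side).  Minus-strand genes are reversed so position 0 is always
    the distal upstream flank and the TSS sits at index
    ``flank_bp // window``.  The profile is the positionwise mean over
    genes, ignoring undefined values.

    Accepts either a BinTrack at ``window`` resolution or a methylation
    call table (converted internally for the given context).
    """
    if isinstance(track_or_calls, BinTrack):
        track = track_or_calls
        if track.resolution != window:
            raise ValueError("track resolution must equal the window size")
    else:
        track = chromosome_profile(
            track_or_calls, context, bin=window, layout=layout
        )
    n_flank = flank_bp // window
    width = n_flank + body_bins + n_flank
    acc = np.zeros(width)
    cnt = np.zeros(width)
    per_chrom = {
        c: track.values[track.chrom_slice(c)]
        for c in dict.fromkeys(track.bins["chrom"])
    }
    for _, g in genes.iterrows():
        if g["start"] >= g["end"]:
            raise ValueError(
                f"gene {g.get('gene_id', '?')!r} has start >= end"
            )
        vals = per_chrom.get(g["chrom"])
        if vals is None:
            continue
        nwin = vals.size
        if (g["end"] - g["start"]) < window:
            continue
        prof = np.full(width, np.nan)
        # flanks in absolute windows
        tss_w = g["start"] // window
        tts_w = (g["end"] - 1) // window
        for k in range(n_flank):
            up = tss_w - n_flank + k
            dn = tts_w + 1 + k
            if 0 <= up < nwin:
                prof[k] = vals[up]
            if 0 <= dn < nwin:
                prof[n_flank + body_bins + k] = vals[dn]
        # body rescaled to body_bins positions
        edges = np.linspace(g["start"], g["end"], body_bins + 1)
        for b in range(body_bins):
            w0 = int(edges[b] // window)
            w1 = int(np.ceil(edges[b + 1] / window))
            w0, w1 = max(w0, 0), min(w1, nwin)
            if w1 <= w0:
                continue
            seg_vals, weights = [], []
            for w in range(w0, w1):
                ov = min(edges[b + 1], (w + 1) * window) - max(
                    edges[b], w * window
                )
                if ov > 0 and not np.isnan(vals[w]):
                    seg_vals.append(vals[w])
                    weights.append(ov)
            if seg_vals:
                prof[n_flank + b] = np.average(seg_vals, weights=weights)
        if g["strand"] == "-":
            prof = prof[::-1]
        ok = ~np.isnan(prof)
        acc[ok] += prof[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
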