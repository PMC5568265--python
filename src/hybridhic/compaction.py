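"""Chromatin compactness, interaction decay exponents, and region scores.

Compactness of a 5-kb bin is the sum of its balanced, lag-1-scaled
interactions with all bins 10-50 kb away (lags 2..10 in bins, both
directions; up to 18 candidate entries for an interior bin).  Because
every map is first scaled so the mean 5-kb-apart interaction is 1, the
statistic is invariant to sequencing depth and the values of two maps
(hybrid vs parent) are directly comparable as ratios.

The interaction decay exponent of a 100-kb region is the slope of
log(mean interaction) against log(genomic distance) over the 5..50-kb
lags computed inside that region, fitted by least squares; shallower
(less negative) slopes indicate more compact, heterochromatin-like
packing.  Regions retaining fewer than six valid lag means carry no
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, mean_at_lag, scale_by_reference_lag
from .tracks import BinTrack

COMPACT_LAG_MIN = 2
COMPACT_LAG_MAX = 10
N_CANDIDATE_LAGS = 2 * (COMPACT_LAG_MAX - COMPACT_LAG_MIN + 1)  # 18
MIN_VALID_FRACTION = 0.8
DECAY_LAGS = tuple(range(1, 11))
MIN_LAG_MEANS = 6


@dataclass
class CompactnessProfile:
    """Per-bin compactness K with the count of valid lag entries."""

    track: BinTrack
    n_valid: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.track.values

    @property
    def bins(self) -> pd.DataFrame:
        return self.track.bins


@dataclass
class DecayExponentTrack:
    """Per-window decay exponent with the number of lag means used."""

    track: BinTrack
    n_lags: np.ndarray


def _require_scaled(matrix: ContactMatrix) -> ContactMatrix:
    if matrix.state == "scaled":
        return matrix
    if matrix.state == "balanced":
        return scale_by_reference_lag(matrix, lag=1)
    raise ValueError("matrix must be balanced (or already scaled)")


def bin_compactness(
    matrix: ContactMatrix,
    any_resolution: bool = False,
    min_valid_fraction: float = MIN_VALID_FRACTION,
) -> CompactnessProfile:
    """Compactness K_i = Σ value(i, j) over 10-50 kb neighbours.

    At 5-kb resolution the window is lags 2..10; with
    ``any_resolution`` the lags are rescaled to keep the physical
    10-50 kb span.  K is defined only where at least
    ``min_valid_fraction`` of the 18 candidate lag entries exist within
    the chromosome with both bins unmasked.
    """
    if matrix.resolution != 5_000 and not any_resolution:
        raise ValueError(
            "compactness is defined on 5-kb maps; pass any_resolution=True "
            "to rescale the 10-50 kb window"
        )
    lag_min = max(1, int(round(10_000 / matrix.resolution)))
    lag_max = max(lag_min, int(round(50_000 / matrix.resolution)))
    n_candidates = 2 * (lag_max - lag_min + 1)
    need = int(np.ceil(min_valid_fraction * n_candidates))

    m = _require_scaled(matrix)
    sym = m.symmetric()
    n = m.n_bins
    K = np.zeros(n)
    n_valid = np.zeros(n, dtype=int)
    for chrom in m.chrom_names:
        lo, hi = m.chrom_bin_range(chrom)
        sub = sym[lo:hi, lo:hi].toarray()
        mask = m.mask[lo:hi]
        nb = hi - lo
        for off in range(lag_min, lag_max + 1):
            for sign in (+1, -1):
                i = np.arange(nb)
                j = i + sign * off
                ok = (j >= 0) & (j < nb)
                i, j = i[ok], j[ok]
                good = ~mask[i] & ~mask[j]
                K[lo + i[good]] += sub[i[good], j[good]]
                n_valid[lo + i[good]] += 1
    values = np.where(n_valid >= need, K, np.nan)
    values[m.mask] = np.nan
    track = BinTrack(
        m.bins.copy(), values, m.resolution, name="compactness"
    )
    return CompactnessProfile(track, n_valid)


def compactness_ratio(
    profile_num: CompactnessProfile,
    profile_den: CompactnessProfile,
    quantile: float = 0.10,
) -> tuple[BinTrack, np.ndarray, np.ndarray]:
    """Per-bin K ratio with bottom/top quantile bin sets.

    The ratio is defined only where both profiles are defined and the
    denominator is positive.  The bottom/top sets are the lowest and
    highest ``quantile`` of defined ratios; ties break by genomic
    coordinate (stable sort), so the sets are reproducible.
    """
    if not profile_num.track.same_bins(profile_den.track):
        raise ValueError("profiles are on different bins")
    num = profile_num.values
    den = profile_den.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            ~np.isnan(num) & ~np.isnan(den) & (den > 0), num / den, np.nan
        )
    track = BinTrack(
        profile_num.bins.copy(),
        ratio,
        profile_num.track.resolution,
        name="compactness_ratio",
    )
    defined = np.flatnonzero(~np.isnan(ratio))
    k = int(np.floor(quantile * defined.size))
    order = defined[np.argsort(ratio[defined], kind="stable")]
    bottom = np.sort(order[:k])
    top = np.sort(order[defined.size - k :]) if k else np.array([], dtype=int)
    return track, bottom, top


def decay_exponent_track(
    matrix: ContactMatrix, window: int = 100_000
) -> DecayExponentTrack:
    """Windowed interaction decay exponents from a balanced 5-kb map.

    Windows are non-overlapping, left-aligned per chromosome; trailing
    partial windows are dropped.  Within a window, the mean unmasked
    entry value at each lag 1..10 is computed over bin pairs with both
    bins inside the window; empty or all-zero lag means are dropped and
    at least six must remain for a least-squares fit of log(mean) vs
    log(distance).
    """
    if matrix.state not in ("balanced", "scaled"):
        raise ValueError("matrix must be balanced")
    r = matrix.resolution
    if window % r != 0:
        raise ValueError("window must be an integer multiple of resolution")
    wbins = window // r
    if wbins < MIN_LAG_MEANS:
        raise ValueError("window too small for six lag means")
    sym = matrix.symmetric()
    rows = []
    slopes = []
    nlags = []
    for chrom in matrix.chrom_names:
        lo, hi = matrix.chrom_bin_range(chrom)
        sub = sym[lo:hi, lo:hi].toarray()
        mask = matrix.mask[lo:hi]
        nb = hi - lo
        for w0 in range(0, nb - wbins + 1, wbins):
            w1 = w0 + wbins
            dists, means = [], []
            for lag in DECAY_LAGS:
                i = np.arange(w0, w1 - lag)
                if i.size == 0:
                    continue
                j = i + lag
                ok = ~mask[i] & ~mask[j]
                if not ok.any():
                    continue
                mval = sub[i[ok], j[ok]].mean()
                if mval <= 0:
                    continue  # log undefined; treat like a missing lag
                dists.append(lag * r)
                means.append(mval)
            start = matrix.bins["start"].iloc[lo + w0]
            rows.append((chrom, int(start), int(start) + window))
            if len(means) >= MIN_LAG_MEANS:
                slope = np.polyfit(np.log(dists), np.log(means), 1)[0]
                slopes.append(float(slope))
            else:
                slopes.append(np.nan)
            nlags.append(len(means))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    track = BinTrack(
        bins, np.array(slopes), window, name="decay_exponent"
    )
    return DecayExponentTrack(track, np.array(nlags, dtype=int))


def chromosome_decay_curve(
    matrix: ContactMatrix, max_distance: int | None = None
) -> pd.DataFrame:
    """Per-chromosome relative contact frequency vs distance.

    Mean unmasked value per lag, normalized so the curve at one bin of
    distance (20 kb on a 20-kb map) equals exactly 1.
    """
    if matrix.state not in ("balanced", "scaled"):
        raise ValueError("matrix must be balanced")
    r = matrix.resolution
    rows = []
    for chrom in matrix.chrom_names:
        lo, hi = matrix.chrom_bin_range(chrom)
        sub = ContactMatrix(
            matrix.bins.iloc[lo:hi].reset_index(drop=True),
            matrix.values[lo:hi, lo:hi].tocsr(),
            matrix.mask[lo:hi],
            r,
            state=matrix.state,
        )
        nb = hi - lo
        max_lag = nb - 1
        if max_distance is not None:
            max_lag = min(max_lag, max_distance // r)
        ref = mean_at_lag(sub, 1)  # raises if no unmasked lag-1 entries
        if ref <= 0:
            raise ValueError(
                f"no positive lag-1 signal on chromosome {chrom!r}"
            )
        for lag in range(1, max_lag + 1):
            try:
                m = mean_at_lag(sub, lag)
            except ValueError:
                continue
            rows.append((chrom, lag * r, m / ref))
    return pd.DataFrame(rows, columns=["chrom", "distance", "rel_frequency"])


def _bins_in_regions(
    matrix: ContactMatrix, regions: pd.DataFrame
) -> np.ndarray:
    hits = []
    for _, reg in regions.iterrows():
        if reg["chrom"] not in matrix.chrom_names:
            raise ValueError(f"region chromosome {reg['chrom']!r} unknown")
        lo, hi = matrix.chrom_bin_range(reg["chrom"])
        starts = matrix.bins["start"].to_numpy()[lo:hi]
        ends = matrix.bins["end"].to_numpy()[lo:hi]
        sel = (ends > reg["start"]) & (starts < reg["end"])
        hits.append(lo + np.flatnonzero(sel))
    return np.unique(np.concatenate(hits)) if hits else np.array([], int)


def aggregate_region_interactions(
    matrix: ContactMatrix,
    regions_a: pd.DataFrame,
    regions_b: pd.DataFrame,
    scope: str = "both",
    flank: int | None = None,
) -> dict:
    """Mean balanced interaction between two region sets.

    Averages unmasked matrix entries over unordered bin pairs {i, j}
    with i in A-bins, j in B-bins, i != j, restricted to cis, trans or
    both.  With ``flank``, also reports the contrast against A's direct
    flanks (mean over A x A-flank pairs), the comparison used to ask
    whether heterochromatin islands re-engage their euchromatic
    surroundings.
    """
    if len(regions_a) == 0 or len(regions_b) == 0:
        raise ValueError("region sets must be non-empty")
    if scope not in ("cis", "trans", "both"):
        raise ValueError(f"unknown scope {scope!r}")

    def pair_mean(bins_a, bins_b):
        sym = matrix.symmetric()
        chrom_of = matrix.bins["chrom"].to_numpy()
        seen = set()
        total, count = 0.0, 0
        for i in bins_a:
            if matrix.mask[i]:
                continue
            for j in bins_b:
                if j == i or matrix.mask[j]:
                    continue
                same = chrom_of[i] == chrom_of[j]
                if scope == "cis" and not same:
                    continue
                if scope == "trans" and same:
                    continue
                key = (min(i, j), max(i, j))
                if key in seen:
                    continue
                seen.add(key)
                total += sym[key]
                count += 1
        return (total / count if count else None), count

    bins_a = _bins_in_regions(matrix, regions_a)
    bins_b = _bins_in_regions(matrix, regions_b)
    mean_ab, n_ab = pair_mean(bins_a, bins_b)
    result = {"mean": mean_ab, "n": n_ab}
    if mean_ab is None:
        result["note"] = "no eligible unmasked bin pairs"
    if flank is not None:
        fl = []
        for _, reg in regions_a.iterrows():
            fl.append(
                {
                    "chrom": reg["chrom"],
                    "start": max(0, reg["start"] - flank),
                    "end": reg["start"],
                }
            )
            fl.append(
                {
                    "chrom": reg["chrom"],
                    "start": reg["end"],
                    "end": reg["end"] + flank,
                }
            )
        flank_df = pd.DataFrame(fl)
        flank_df = flank_df[flank_df["end"] > flank_df["start"]]
        bins_f = _bins_in_regions(matrix, flank_df)
        bins_f = np.setdiff1d(bins_f, bins_a)
        if bins_f.size:
            mean_af, n_af = pair_mean(bins_a, bins_f)
            result["flank_mean"] = mean_af
            result["flank_n"] = n_af
        else:
            result["flank_mean"] = None
            result["flank_n"] = 0
    return result
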