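"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from hybridhic.contacts import ContactMatrix
from hybridhic.tracks import BinTrack


def dense_to_matrix(
    dense: np.ndarray,
    resolution: int = 5_000,
    state: str = "balanced",
    chrom: str = "chr1",
    mask: np.ndarray | None = None,
) -> ContactMatrix:
    """ContactMatrix from a dense symmetric array (single chromosome)."""
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * resolution,
            "end": (np.arange(n) + 1) * resolution,
        }
    )
    upper = sp.csr_matrix(np.triu(dense))
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    return ContactMatrix(bins, upper, np.asarray(mask, bool), resolution, state=state)


def power_law_matrix(
    n: int, alpha: float, resolution: int = 5_000, state: str = "balanced"
) -> ContactMatrix:
    """Noise-free c(d) = (d / resolution)^alpha matrix, zero diagonal."""
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        dense = np.where(d > 0, d**alpha, 0.0)
    return dense_to_matrix(dense, resolution=resolution, state=state)


def track_from_values(values, resolution: int = 5_000, chrom: str = "chr1") -> BinTrack:
    values = np.asarray(values, dtype=float)
    n = values.size
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * resolution,
            "end": (np.arange(n) + 1) * resolution,
        }
    )
    return BinTrack(bins, values, resolution)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ice_oracle(dense: np.ndarray, n_iter: int = 5_000) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force fixed-point iteration: divide by marginals until stable."""
    w = np.asarray(dense, dtype=float).copy()
    n = w.shape[0]
    bias = np.ones(n)
    for _ in range(n_iter):
        m = w.sum(axis=1)
        s = m / m.mean()
        bias *= s
        w = w / np.outer(s, s)
    return w, bias


def decay_slope_oracle(
    dense: np.ndarray, mask: np.ndarray, w0: int, w1: int, resolution: int
) -> tuple[float | None, int]:
    """Explicit-loop decay exponent for window [w0, w1) of a dense matrix."""
    dists, means = [], []
    for lag in range(1, 11):
        vals = []
        for i in range(w0, w1 - lag):
            j = i + lag
            if not mask[i] and not mask[j]:
                vals.append(dense[i, j])
        if vals:
            m = sum(vals) / len(vals)
            if m > 0:
                dists.append(lag * resolution)
                means.append(m)
    if len(means) < 6:
        return None, len(means)
    x = np.log(dists)
    y = np.log(means)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return float(slope), len(means)


def mark_bitmap_oracle(genes: pd.DataFrame, peaks: pd.DataFrame, min_fraction: float) -> set:
    """Per-base bitmap gene marking (exact, slow)."""
    marked = set()
    for _, g in genes.iterrows():
        length = g["end"] - g["start"]
        if length <= 0:
            continue
        bitmap = np.zeros(length, dtype=bool)
        for _, p in peaks[peaks["chrom"] == g["chrom"]].iterrows():
            lo = max(p["start"], g["start"]) - g["start"]
            hi = min(p["end"], g["end"]) - g["start"]
            if hi > lo:
                bitmap[lo:hi] = True
        if bitmap.sum() > min_fraction * length:
            marked.add(g["gene_id"])
    return marked


def rank_sum_exact_oracle(x, y, alternative: str = "greater") -> float:
    """Exact Wilcoxon-Mann-Whitney p by enumeration over all splits."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n = len(x)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)  # rank sum of x (tie-free)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n):
        rs = sum(sorted(pooled).index(pooled[k]) + 1 for k in combo)
        rs = sum(ranks[pooled[k]] for k in combo)
        total += 1
        if alternative == "greater" and rs >= obs:
            count += 1
        elif alternative == "less" and rs <= obs:
            count += 1
        elif alternative == "two-sided":
            mu = n * (len(pooled) + 1) / 2
            if abs(rs - mu) >= abs(obs - mu):
                count += 1
    return count / total
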