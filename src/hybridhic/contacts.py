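"""Binned cis contact matrices: construction, masking, ICE balancing, scaling.

The matrix is stored upper-triangular sparse over genome-wide bins;
symmetry is a presentation contract (``value(i, j) == value(j, i)``).
Coordinates are 0-based half-open, bin index ``pos // resolution``, and
the distance between bins i and j is ``|i - j| * resolution``.

Balancing follows the iterative correction (ICE) idea: every unmasked
bin should have equal visibility, so rows/columns are repeatedly divided
by their marginals until the bias vector stops moving.  The stopping
rule is the maximum absolute relative change of the bias vector between
consecutive iterations dropping below ``eps`` (default 1e-4).  Bias- and
matrix-change criteria agree up to constants; the bias change is cheaper
to evaluate.  Normalization runs genome-wide for coarse (20-kb) maps and
per chromosome for fine (5-kb) maps, selectable via ``unit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .layout import GenomeLayout
from .tracks import tile_genome


@dataclass
class ContactMatrix:
    """Symmetric cis contact matrix over genome-tiling bins.

    ``values`` stores the upper triangle (i <= j) as CSR; ``mask`` is
    True for excluded bins; ``state`` is one of raw/balanced/scaled.
    """

    bins: pd.DataFrame  # chrom, start, end, global bin order
    values: sp.csr_matrix
    mask: np.ndarray
    resolution: int
    state: str = "raw"
    unit: str = "genome"
    trans_dropped: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        return int(idx[0]), int(idx[-1]) + 1

    @property
    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def unit_slices(self, unit: str | None = None) -> list[slice]:
        unit = unit or self.unit
        if unit == "genome":
            return [slice(0, self.n_bins)]
        if unit == "chromosome":
            return [
                slice(*self.chrom_bin_range(c)) for c in self.chrom_names
            ]
        raise ValueError(f"unknown normalization unit {unit!r}")

    def value(self, i: int, j: int) -> float:
        a, b = (i, j) if i <= j else (j, i)
        return float(self.values[a, b])

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal counted once)."""
        upper = sp.triu(self.values, k=0)
        return (upper + sp.triu(self.values, k=1).T).tocsr()

    def marginals(self) -> np.ndarray:
        return np.asarray(self.symmetric().sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return self.symmetric().toarray()

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bins.copy(),
            self.values.copy(),
            self.mask.copy(),
            self.resolution,
            state=self.state,
            unit=self.unit,
            trans_dropped=self.trans_dropped,
        )

    def total_count(self) -> float:
        return float(self.values.sum())


@dataclass
class BiasVector:
    """Per-bin multiplicative visibility biases from iterative correction."""

    values: np.ndarray  # NaN at masked bins; gauge: geometric mean == 1
    eps_achieved: float
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_contacts(
    pairs: pd.DataFrame,
    layout: GenomeLayout,
    resolution: int,
    trans_policy: str = "drop",
) -> ContactMatrix:
    """Bin a contact-pair table into a cis ContactMatrix.

    Each cis pair increments exactly one upper-triangle cell; trans
    pairs are dropped and counted in ``trans_dropped``.  Pairs naming an
    unknown chromosome or out-of-bounds position are rejected with the
    offending row number.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    bins = tile_genome(layout, resolution)
    offsets = {}
    pos = 0
    for chrom in layout.chrom_names:
        n = -(-layout.length(chrom) // resolution)
        offsets[chrom] = pos
        pos += n
    n_bins = pos

    if len(pairs):
        for col in ("chrom1", "chrom2"):
            known = pairs[col].isin(offsets)
            if not known.all():
                row = int(np.flatnonzero(~known.to_numpy())[0])
                raise ValueError(
                    f"pair row {row}: unknown chromosome "
                    f"{pairs[col].iloc[row]!r}"
                )
        for ccol, pcol in (("chrom1", "pos1"), ("chrom2", "pos2")):
            lens = pairs[ccol].map(
                {c: layout.length(c) for c in layout.chrom_names}
            )
            bad = (pairs[pcol] < 0) | (pairs[pcol] >= lens)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"pair row {row}: position out of bounds")

    cis = pairs[pairs["chrom1"] == pairs["chrom2"]] if len(pairs) else pairs
    trans_dropped = len(pairs) - len(cis)
    if len(cis):
        off = cis["chrom1"].map(offsets).to_numpy()
        b1 = off + (cis["pos1"].to_numpy() // resolution)
        b2 = off + (cis["pos2"].to_numpy() // resolution)
        counts = (
            cis["count"].to_numpy()
            if "count" in cis.columns
            else np.ones(len(cis), dtype=int)
        )
        i = np.minimum(b1, b2)
        j = np.maximum(b1, b2)
        mat = sp.coo_matrix(
            (counts.astype(float), (i, j)), shape=(n_bins, n_bins)
        ).tocsr()
        mat.sum_duplicates()
    else:
        mat = sp.csr_matrix((n_bins, n_bins))
    return ContactMatrix(
        bins,
        mat,
        np.zeros(n_bins, dtype=bool),
        resolution,
        state="raw",
        trans_dropped=int(trans_dropped),
    )


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def mask_low_coverage(
    matrix: ContactMatrix,
    quantile: float = 0.01,
    layout: GenomeLayout | None = None,
) -> ContactMatrix:
    """Mask invisible bins before balancing.

    Zero-marginal bins are always masked; bins whose marginal falls
    strictly below the ``quantile`` quantile of the *nonzero* marginals
    are additionally masked; layout segments labelled ``masked`` (N
    runs) are force-masked.  Entries touching masked bins are removed.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    if matrix.state != "raw":
        raise ValueError("masking applies to raw matrices")
    out = matrix.copy()
    marg = out.marginals()
    mask = marg == 0
    nonzero = marg[marg > 0]
    if quantile > 0 and nonzero.size:
        thr = np.quantile(nonzero, quantile)
        mask |= marg < thr
    if layout is not None:
        for _, seg in layout.masked_intervals().iterrows():
            lo, hi = out.chrom_bin_range(seg["chrom"])
            starts = out.bins["start"].to_numpy()[lo:hi]
            first = lo + np.searchsorted(
                starts, seg["start"] - out.resolution + 1
            )
            last = lo + np.searchsorted(starts, seg["end"])
            # bins fully inside the masked interval
            for b in range(first, last):
                s = out.bins["start"].iloc[b]
                e = out.bins["end"].iloc[b]
                if s >= seg["start"] and e <= seg["end"]:
                    mask[b] = True
    out.mask |= mask
    out.values = _zero_masked(out.values, out.mask)
    return out


def _zero_masked(values: sp.csr_matrix, mask: np.ndarray) -> sp.csr_matrix:
    if not mask.any():
        return values
    keep = sp.diags((~mask).astype(float))
    return (keep @ values @ keep).tocsr()


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def ice_normalize(
    matrix: ContactMatrix,
    eps: float = 1e-4,
    max_iter: int = 200,
    unit: str | None = None,
) -> tuple[ContactMatrix, BiasVector]:
    """Iterative correction to equal per-bin visibility.

    Per normalization unit (whole genome or one chromosome), rows and
    columns are divided by their marginals (normalized to unit mean over
    unmasked bins) until the max absolute relative change of the bias
    vector drops below ``eps``.  The returned bias vector has geometric
    mean 1 over unmasked bins; masked bins carry NaN.
    """
    if matrix.state != "raw":
        raise ValueError("ice_normalize expects a raw (masked) matrix")
    unit = unit or ("genome" if matrix.resolution >= 20_000 else "chromosome")
    out = matrix.copy()
    out.unit = unit
    n = out.n_bins
    bias = np.ones(n)
    sym = out.symmetric().tolil().tocsr()
    mask = out.mask
    eps_achieved = np.inf
    iterations = 0
    converged = False

    slices = out.unit_slices(unit)
    active = ~mask
    for sl in slices:
        if active[sl].sum() == 0:
            continue
        if active[sl].sum() < 2:
            raise ValueError(
                "need at least 2 unmasked bins per normalization unit"
            )

    work = sym.astype(float)
    for it in range(1, max_iter + 1):
        marg = np.asarray(work.sum(axis=1)).ravel()
        s = np.ones(n)
        for sl in slices:
            act = active[sl]
            if act.sum() == 0:
                continue
            m = marg[sl]
            mean = m[act].mean()
            if mean <= 0:
                continue
            # sqrt damping keeps the same fixed point but prevents the
            # period-2 oscillation between chromosomes of a cis-only
            # (block-diagonal) map under genome-wide normalization
            s_local = np.where(act, np.sqrt(m / mean), 1.0)
            s_local[s_local == 0] = 1.0
            s[sl] = s_local
        new_bias = bias * s
        d = sp.diags(1.0 / s)
        work = (d @ work @ d).tocsr()
        rel = np.abs(new_bias - bias) / np.where(bias > 0, bias, 1.0)
        eps_achieved = float(rel[active].max()) if active.any() else 0.0
        bias = new_bias
        iterations = it
        if eps_achieved < eps:
            converged = True
            break

    # gauge: geometric mean of unmasked biases == 1 within each unit
    for sl in slices:
        act = active[sl]
        if not act.any():
            continue
        gm = np.exp(np.mean(np.log(bias[sl][act])))
        bias[sl] = bias[sl] / np.where(act, gm, 1.0)
    # rebuild the balanced matrix from the original counts and final biases
    inv = np.zeros(n)
    inv[active] = 1.0 / bias[active]
    d = sp.diags(inv)
    balanced_sym = (d @ sym @ d).tocsr()
    out.values = sp.triu(balanced_sym, k=0).tocsr()
    out.state = "balanced"

    bias_out = bias.copy()
    bias_out[mask] = np.nan
    return out, BiasVector(bias_out, eps_achieved, iterations, converged)


# ---------------------------------------------------------------------------
# reference-lag scaling
# ---------------------------------------------------------------------------

def mean_at_lag(
    matrix: ContactMatrix, lag: int, sl: slice | None = None
) -> float:
    """Mean value over all unmasked same-chromosome bin pairs at |i-j| == lag.

    Implicit zeros between unmasked bins count toward the mean.
    """
    sym = matrix.symmetric()
    total = 0.0
    count = 0
    for chrom in matrix.chrom_names:
        lo, hi = matrix.chrom_bin_range(chrom)
        if sl is not None and (lo < sl.start or hi > sl.stop):
            continue
        n = hi - lo
        if n <= lag:
            continue
        i = np.arange(lo, hi - lag)
        j = i + lag
        ok = ~matrix.mask[i] & ~matrix.mask[j]
        if not ok.any():
            continue
        vals = np.asarray(sym[i[ok], j[ok]]).ravel()
        total += vals.sum()
        count += int(ok.sum())
    if count == 0:
        raise ValueError(f"no unmasked entries at lag {lag}")
    return total / count


def scale_by_reference_lag(
    matrix: ContactMatrix, lag: int = 1, unit: str | None = None
) -> ContactMatrix:
    """Divide every entry by the mean unmasked entry at the reference lag.

    After scaling the mean at that lag is exactly 1 within each
    normalization unit, making maps of different sequencing depth
    comparable.  Idempotent for a fixed lag.
    """
    if matrix.state not in ("balanced", "scaled"):
        raise ValueError("scale_by_reference_lag expects a balanced matrix")
    unit = unit or matrix.unit
    out = matrix.copy()
    out.unit = unit
    scale = np.ones(out.n_bins)
    for sl in out.unit_slices(unit):
        sub = ContactMatrix(
            out.bins.iloc[sl.start : sl.stop].reset_index(drop=True),
            out.values[sl, sl].tocsr(),
            out.mask[sl],
            out.resolution,
            state=out.state,
        )
        m = mean_at_lag(sub, lag)
        scale[sl] = np.sqrt(m)
    d = sp.diags(1.0 / scale)
    out.values = (d @ out.values @ d).tocsr()
    out.state = "scaled"
    return out
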