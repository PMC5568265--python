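"""Synthetic hybrid data with known ground truth.

Emulates, at desk scale, the data types of an interspecific plant-hybrid
epigenome study: a two-subgenome reference (5 "thaliana-like" chromosomes
labelled A plus 8 "lyrata-like" chromosomes labelled B and numbered 6-13),
cis Hi-C contact pairs with power-law distance decay and multiplicative
per-bin visibility biases, beta-binomial bisulfite methylomes whose CHH
level tracks TE density, H3K27me3/H3 coverage with gene-body peaks, a
parent/hybrid expression table in which H3K27me3-marked subgenome-A genes
receive a negative shift and inflated variance of the hybrid:parent log2
ratio, and confocal FISH z-stacks with analytically known signal volumes.

All randomness flows from one ``numpy.random.Generator`` seeded by the
required ``seed`` field; identical parameters and seed reproduce outputs
byte for byte.

Chromosome lengths default to ~1/20 of the real genomes (1.5 Mb) so that
full pipelines run in minutes on one CPU; every size is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout
from .tracks import BinTrack, tile_genome


@dataclass
class SimulationParams:
    """All knobs of the synthetic world.  ``seed`` is required.

    Decay exponents ``alpha_*`` are the slopes of log contact frequency
    vs log distance; arms default to -1.0 and pericentromeres to -0.6 so
    heterochromatin is the more compact (shallower-decaying) compartment.
    ``alpha_overrides`` maps ``(subgenome, segment-label)`` to an exponent
    and is how a "hybrid" map injects extra subgenome-A compaction.
    """

    seed: int
    resolution: int = 5_000

    # genome layout
    n_chrom_a: int = 5
    n_chrom_b: int = 8
    chrom_length_a: int = 1_500_000
    chrom_length_b: int = 1_500_000
    pericentromere_fraction: float = 0.2
    masked_fraction: float = 0.04
    te_window: int = 10_000
    te_arm_a: float = 0.08
    te_ratio: float = 5.0  # B-arm over A-arm mean TE density
    te_pericentromere: float = 0.8
    te_noise_sd: float = 0.02

    # Hi-C
    alpha_arm: float = -1.0
    alpha_pericentromere: float = -0.6
    alpha_overrides: dict = field(default_factory=dict)
    bias_sd: float = 0.25
    n_pairs: int = 1_000_000
    trans_rate: float = 0.0

    # methylome
    meth_means: dict = field(
        default_factory=lambda: {"CG": 0.24, "CHG": 0.10, "CHH": 0.04}
    )
    meth_te_coupling: dict = field(
        default_factory=lambda: {"CG": 0.30, "CHG": 0.25, "CHH": 0.40}
    )
    meth_overdispersion: float = 0.05
    meth_coverage: float = 20.0
    site_spacing: int = 300  # bp between consecutive sites of one context

    # genes, marks, expression
    genes_per_mb: float = 200.0
    gene_length: int = 2_000
    marked_fraction: float = 0.22
    mark_concordance: float = 0.85
    mark_gain_rate: float = 0.02
    peak_cover_lo: float = 0.6  # peak covers this..hi of a marked gene body
    peak_cover_hi: float = 0.95
    chip_window: int = 100
    h3_mean_coverage: float = 20.0
    k27_peak_enrichment: float = 4.0
    expr_log_mean: float = 4.0  # log of NB mean counts
    expr_log_sd: float = 1.0
    expr_dispersion: float = 0.1
    marked_a_shift: float = -0.5  # log2 hybrid:parent shift, A-marked genes
    marked_a_extra_sd: float = 0.4
    baseline_ratio_sd: float = 0.15

    # FISH
    fish_shape: tuple = (40, 160, 160)  # slices, rows, cols
    fish_pixel_um: float = 0.05
    fish_slice_um: float = 0.22
    fish_background: float = 5.0
    fish_signal: float = 200.0
    fish_spheres: tuple = ((4.4, 4.0, 4.0, 2.0),)  # (z,y,x, r) in um

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def alpha_for(self, subgenome: str, label: str) -> float:
        base = {
            "arm": self.alpha_arm,
            "pericentromere": self.alpha_pericentromere,
        }.get(label, self.alpha_arm)
        return float(self.alpha_overrides.get((subgenome, label), base))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.alpha_arm > 0 or self.alpha_pericentromere > 0:
            raise ValueError("decay exponents must be <= 0")


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def make_genome_layout(params: SimulationParams) -> GenomeLayout:
    """Build the hybrid reference layout.

    Subgenome-A chromosomes are named chr1..chr5 and subgenome-B
    chromosomes continue as chr6..chr13 (the re-numbering a hybrid
    reference applies to the second parent's chromosomes).  The
    pericentromere is centred; masked (N) segments sit at the centromere
    core inside it.
    """
    chroms = []
    for i in range(params.n_chrom_a):
        chroms.append((f"chr{i + 1}", params.chrom_length_a, "A"))
    for i in range(params.n_chrom_b):
        chroms.append(
            (f"chr{params.n_chrom_a + i + 1}", params.chrom_length_b, "B")
        )
    chrom_df = pd.DataFrame(chroms, columns=["name", "length", "subgenome"])
    for _, row in chrom_df.iterrows():
        if row["length"] <= 0:
            raise ValueError(
                f"chromosome {row['name']!r} has non-positive length"
            )
        if row["length"] < 20 * params.resolution:
            raise ValueError(
                f"chromosome {row['name']!r} shorter than 20 bins"
            )

    seg_rows = []
    for _, row in chrom_df.iterrows():
        name, length = row["name"], int(row["length"])
        peri = int(length * params.pericentromere_fraction)
        mask = int(length * params.masked_fraction)
        if peri <= 0:
            seg_rows.append((name, 0, length, "arm"))
            continue
        mid = length // 2
        p0, p1 = mid - peri // 2, mid + (peri - peri // 2)
        seg_rows.append((name, 0, p0, "arm"))
        if mask > 0:
            m0, m1 = mid - mask // 2, mid + (mask - mask // 2)
            seg_rows.append((name, p0, m0, "pericentromere"))
            seg_rows.append((name, m0, m1, "masked"))
            seg_rows.append((name, m1, p1, "pericentromere"))
        else:
            seg_rows.append((name, p0, p1, "pericentromere"))
        seg_rows.append((name, p1, length, "arm"))
    seg_df = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "label"])

    # TE density: arm level per subgenome, pericentromere level, noise
    rng = params.rng(salt=1)
    te_rows = []
    for _, row in chrom_df.iterrows():
        name, length, sub = row["name"], int(row["length"]), row["subgenome"]
        bins = tile_genome({name: length}, params.te_window)
        mids = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
        arm_level = params.te_arm_a * (params.te_ratio if sub == "B" else 1.0)
        seg = seg_df[seg_df["chrom"] == name]
        starts = seg["start"].to_numpy()
        idx = np.clip(
            np.searchsorted(starts, mids, side="right") - 1, 0, len(seg) - 1
        )
        labels = seg["label"].to_numpy()[idx]
        level = np.where(
            labels == "arm", arm_level, params.te_pericentromere
        ).astype(float)
        level += rng.normal(0.0, params.te_noise_sd, size=level.size)
        bins["value"] = np.clip(level, 0.0, 1.0)
        te_rows.append(bins)
    te_df = pd.concat(te_rows, ignore_index=True)

    return GenomeLayout(chrom_df, seg_df, te_df, te_window=params.te_window)


# ---------------------------------------------------------------------------
# Hi-C contact pairs
# ---------------------------------------------------------------------------

def _bin_segments(layout: GenomeLayout, chrom: str, resolution: int):
    """Per-bin segment label (by bin midpoint) and masked flag."""
    length = layout.length(chrom)
    n = -(-length // resolution)
    mids = np.minimum(
        np.arange(n) * resolution + resolution // 2, length - 1
    )
    labels = layout.segment_label_at(chrom, mids)
    return labels, labels == "masked"


def simulate_contact_pairs(
    layout: GenomeLayout, params: SimulationParams
) -> tuple[pd.DataFrame, dict]:
    """Draw cis contact pairs under E[c_ij] ∝ b_i·b_j·(d_ij/r)^α.

    Counts are a multinomial split of exactly ``n_pairs`` over bin-pair
    cells (Poisson-like at depth, but conserving the total).  Returns the
    pair table (chrom1, pos1, chrom2, pos2, count=1 per row) and a
    ground-truth sidecar with per-bin biases and per-(subgenome, segment)
    decay exponents.  Trans pairs are emitted at ``trans_rate`` (default
    0, matching the analyzed scope of a hybrid whose trans signals are
    mapping-error prone).
    """
    if not layout.chrom_names:
        raise ValueError("layout has no chromosomes")
    r = params.resolution
    rng = params.rng(salt=2)

    n_trans = 0
    if params.trans_rate > 0:
        n_trans = int(round(params.n_pairs * params.trans_rate))
    n_cis = params.n_pairs - n_trans

    chrom_cells = {}  # chrom -> (i_idx, j_idx, weights, biases)
    truth_bias_rows = []
    alpha_rows = []
    seen_alpha = set()
    for chrom in layout.chrom_names:
        sub = layout.subgenome(chrom)
        labels, masked = _bin_segments(layout, chrom, r)
        n = len(labels)
        if params.bias_sd > 0:
            bias = rng.lognormal(mean=0.0, sigma=params.bias_sd, size=n)
        else:
            bias = np.ones(n)
        bias[masked] = 0.0
        iu, ju = np.triu_indices(n, k=1)
        dist = (ju - iu).astype(float)  # in bins; d_ij/r
        alpha_i = np.array(
            [params.alpha_for(sub, l) for l in labels], dtype=float
        )
        pair_alpha = np.where(
            labels[iu] == labels[ju],
            alpha_i[iu],
            0.5 * (alpha_i[iu] + alpha_i[ju]),
        )
        w = bias[iu] * bias[ju] * dist ** pair_alpha
        chrom_cells[chrom] = (iu, ju, w, bias, n)
        for b_idx in range(n):
            truth_bias_rows.append((chrom, b_idx * r, bias[b_idx]))
        for l in ("arm", "pericentromere"):
            key = (sub, l)
            if key not in seen_alpha:
                seen_alpha.add(key)
                alpha_rows.append((sub, l, params.alpha_for(sub, l)))

    sidecar = {
        "bias": pd.DataFrame(
            truth_bias_rows, columns=["chrom", "start", "bias"]
        ),
        "alpha": pd.DataFrame(
            alpha_rows, columns=["subgenome", "segment", "alpha"]
        ),
    }

    if params.n_pairs == 0:
        empty = pd.DataFrame(
            columns=["chrom1", "pos1", "chrom2", "pos2", "count"]
        )
        sidecar["bias"] = sidecar["bias"].iloc[0:0]
        sidecar["alpha"] = sidecar["alpha"].iloc[0:0]
        return empty, sidecar

    # allocate cis pairs across chromosomes proportional to total weight
    chrom_names = list(chrom_cells)
    totals = np.array([chrom_cells[c][2].sum() for c in chrom_names])
    if totals.sum() <= 0:
        raise ValueError("all contact weights are zero")
    alloc = rng.multinomial(n_cis, totals / totals.sum())

    out = []
    for chrom, n_c in zip(chrom_names, alloc):
        if n_c == 0:
            continue
        iu, ju, w, bias, n = chrom_cells[chrom]
        counts = rng.multinomial(n_c, w / w.sum())
        nz = counts > 0
        i_rep = np.repeat(iu[nz], counts[nz])
        j_rep = np.repeat(ju[nz], counts[nz])
        length = layout.length(chrom)
        pos1 = i_rep * r + rng.integers(0, r, size=i_rep.size)
        pos2 = j_rep * r + rng.integers(0, r, size=j_rep.size)
        pos1 = np.minimum(pos1, length - 1)
        pos2 = np.minimum(pos2, length - 1)
        out.append(
            pd.DataFrame(
                {
                    "chrom1": chrom,
                    "pos1": pos1,
                    "chrom2": chrom,
                    "pos2": pos2,
                    "count": 1,
                }
            )
        )

    if n_trans > 0:
        names = np.array(chrom_names)
        c1 = rng.integers(0, len(names), size=n_trans)
        c2 = (c1 + 1 + rng.integers(0, len(names) - 1, size=n_trans)) % len(
            names
        )
        lens1 = np.array([layout.length(c) for c in names[c1]])
        lens2 = np.array([layout.length(c) for c in names[c2]])
        out.append(
            pd.DataFrame(
                {
                    "chrom1": names[c1],
                    "pos1": rng.integers(0, lens1),
                    "chrom2": names[c2],
                    "pos2": rng.integers(0, lens2),
                    "count": 1,
                }
            )
        )

    pairs = pd.concat(out, ignore_index=True)
    return pairs, sidecar


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def simulate_methylome(
    layout: GenomeLayout, params: SimulationParams
) -> pd.DataFrame:
    """Per-cytosine call table (chrom, pos, strand, context, methylated, total).

    Site-level methylation probability is beta-binomial around
    ``context mean + coupling × local TE density`` (clipped to [0, 1]);
    masked segments emit no sites.
    """
    if params.meth_coverage <= 0:
        raise ValueError("coverage parameter must be positive")
    for ctx, m in params.meth_means.items():
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"context mean for {ctx} outside [0, 1]")
    rng = params.rng(salt=3)
    rho = params.meth_overdispersion
    rows = []
    contexts = sorted(params.meth_means)
    for chrom in layout.chrom_names:
        length = layout.length(chrom)
        for k, ctx in enumerate(contexts):
            offset = (k + 1) * params.site_spacing // (len(contexts) + 1)
            pos = np.arange(offset, length, params.site_spacing)
            labels = layout.segment_label_at(chrom, pos)
            pos = pos[labels != "masked"]
            if pos.size == 0:
                continue
            te = layout.te_density_at(chrom, pos)
            p = np.clip(
                params.meth_means[ctx]
                + params.meth_te_coupling.get(ctx, 0.0) * te,
                0.0,
                1.0,
            )
            total = np.maximum(
                rng.poisson(params.meth_coverage, size=pos.size), 1
            )
            if rho > 0:
                interior = (p > 0) & (p < 1)
                p_site = p.copy()
                if interior.any():
                    a = p[interior] * (1 - rho) / rho
                    b = (1 - p[interior]) * (1 - rho) / rho
                    p_site[interior] = rng.beta(a, b)
            else:
                p_site = p
            meth = rng.binomial(total, p_site)
            strand = np.where(pos % 2 == 0, "+", "-")
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "context": ctx,
                        "methylated": meth,
                        "total": total,
                    }
                )
            )
    calls = pd.concat(rows, ignore_index=True)
    return calls.sort_values(["chrom", "pos"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# marks and expression
# ---------------------------------------------------------------------------

def _bh_fdr(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def simulate_marks_and_expression(
    layout: GenomeLayout, params: SimulationParams
) -> dict:
    """Genes, H3K27me3 peaks, coverage tracks, and the expression table.

    Returns a dict with keys ``genes`` (BED-like gene table with
    expression statistics and ground-truth mark flags), ``peaks_parent``
    / ``peaks_hybrid`` (interval DataFrames), ``k27_parent`` /
    ``k27_hybrid`` / ``h3`` (100-bp coverage BinTracks), and ``truth``.

    Marked fraction of genes is ``marked_fraction`` in each subgenome;
    a marked gene's peak covers 60-95% of its body (always > half).
    Subgenome-A genes marked in both parent and hybrid receive a
    ``marked_a_shift`` mean shift and ``marked_a_extra_sd`` extra spread
    of the hybrid:parent log2 expression ratio.
    """
    if not 0.0 <= params.marked_fraction <= 1.0:
        raise ValueError("marked fraction outside [0, 1]")
    rng = params.rng(salt=4)

    # ---- gene placement (uniform over unmasked sequence) ----
    gene_rows = []
    gid = 0
    for chrom in layout.chrom_names:
        length = layout.length(chrom)
        sub = layout.subgenome(chrom)
        n_genes = max(1, int(round(params.genes_per_mb * length / 1e6)))
        spacing = length // n_genes
        glen = params.gene_length
        for k in range(n_genes):
            start = k * spacing + max(0, (spacing - glen) // 2)
            end = min(start + glen, length)
            if end <= start:
                continue
            mid = (start + end) // 2
            if layout.segment_label_at(chrom, mid)[0] == "masked":
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(
                (f"g{gid:05d}", chrom, start, end, strand, sub)
            )
            gid += 1
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "subgenome"],
    )
    n = len(genes)

    # ---- ground-truth marking ----
    marked_parent = rng.random(n) < params.marked_fraction
    keep = rng.random(n) < params.mark_concordance
    gain = rng.random(n) < params.mark_gain_rate
    marked_hybrid = (marked_parent & keep) | (~marked_parent & gain)
    genes["k27_parent"] = marked_parent
    genes["k27_hybrid"] = marked_hybrid

    def peaks_for(flags: np.ndarray) -> pd.DataFrame:
        rows = []
        for _, g in genes[flags].iterrows():
            glen = g["end"] - g["start"]
            cover = rng.uniform(params.peak_cover_lo, params.peak_cover_hi)
            span = max(int(glen * cover), glen // 2 + 1)
            off = rng.integers(0, max(1, glen - span + 1))
            rows.append((g["chrom"], g["start"] + off, g["start"] + off + span))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return df.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    peaks_parent = peaks_for(marked_parent)
    peaks_hybrid = peaks_for(marked_hybrid)

    # ---- coverage tracks at chip_window resolution ----
    bins = tile_genome(layout, params.chip_window)
    h3 = rng.poisson(params.h3_mean_coverage, size=len(bins)).astype(float)

    def k27_track(peaks: pd.DataFrame) -> BinTrack:
        enrich = np.ones(len(bins))
        starts = bins["start"].to_numpy()
        chroms = bins["chrom"].to_numpy()
        for chrom in layout.chrom_names:
            sel = np.flatnonzero(chroms == chrom)
            if sel.size == 0:
                continue
            cs = starts[sel]
            pk = peaks[peaks["chrom"] == chrom]
            for _, p in pk.iterrows():
                lo = np.searchsorted(cs, p["start"] - params.chip_window + 1)
                hi = np.searchsorted(cs, p["end"])
                enrich[sel[lo:hi]] = params.k27_peak_enrichment
        vals = rng.poisson(params.h3_mean_coverage * enrich).astype(float)
        return BinTrack(bins.copy(), vals, params.chip_window, name="H3K27me3")

    k27_parent = k27_track(peaks_parent)
    k27_hybrid = k27_track(peaks_hybrid)
    h3_track = BinTrack(bins.copy(), h3, params.chip_window, name="H3")

    # ---- expression ----
    log_mu = rng.normal(params.expr_log_mean, params.expr_log_sd, size=n)
    mu_parent = np.exp(log_mu)
    affected = (genes["subgenome"] == "A").to_numpy() & marked_parent & marked_hybrid
    shift = np.where(affected, params.marked_a_shift, 0.0)
    sd = np.sqrt(
        params.baseline_ratio_sd**2
        + np.where(affected, params.marked_a_extra_sd**2, 0.0)
    )
    delta = rng.normal(shift, sd)  # true log2 hybrid:parent ratio
    mu_hybrid = mu_parent * 2.0**delta

    def nb_sample(mu: np.ndarray) -> np.ndarray:
        disp = params.expr_dispersion
        if disp <= 0:
            return rng.poisson(mu)
        shape = 1.0 / disp
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam)

    cp = nb_sample(mu_parent)
    ch = nb_sample(mu_hybrid)
    genes["parent_count"] = cp
    genes["hybrid_count"] = ch
    genes["log2fc"] = np.log2((ch + 0.5) / (cp + 0.5))
    genes["true_log2_ratio"] = delta

    # generator-side DE statistic: two-sided normal test of the hybrid
    # fraction of pooled counts against 0.5 (equal library depth), BH-adjusted
    tot = cp + ch
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ch - tot * 0.5) / np.sqrt(np.maximum(tot * 0.25, 1e-12))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(np.where(tot > 0, pvals, 1.0), 0.0, 1.0)
    genes["fdr"] = _bh_fdr(pvals)

    truth = {
        "marked_parent": set(genes.loc[genes["k27_parent"], "gene_id"]),
        "marked_hybrid": set(genes.loc[genes["k27_hybrid"], "gene_id"]),
        "shift": params.marked_a_shift,
        "extra_sd": params.marked_a_extra_sd,
    }
    return {
        "genes": genes,
        "peaks_parent": peaks_parent,
        "peaks_hybrid": peaks_hybrid,
        "k27_parent": k27_parent,
        "k27_hybrid": k27_hybrid,
        "h3": h3_track,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# FISH stacks
# ---------------------------------------------------------------------------

def simulate_fish_stack(params: SimulationParams) -> tuple[np.ndarray, dict]:
    """Confocal z-stack with ellipsoidal signal domains.

    Background is Poisson noise well below the detection threshold;
    each sphere/ellipsoid is painted at ``fish_signal``.  The sidecar
    records the analytic volume 4/3·π·abc of every domain in μm³.
    """
    nz, ny, nx = params.fish_shape
    if params.fish_pixel_um <= 0 or params.fish_slice_um <= 0:
        raise ValueError("voxel dimensions must be positive")
    rng = params.rng(salt=5)
    stack = rng.poisson(params.fish_background, size=(nz, ny, nx)).astype(
        np.float64
    )
    zc = (np.arange(nz) + 0.5) * params.fish_slice_um
    yc = (np.arange(ny) + 0.5) * params.fish_pixel_um
    xc = (np.arange(nx) + 0.5) * params.fish_pixel_um
    volumes = []
    for dom in params.fish_spheres:
        if len(dom) == 4:
            z0, y0, x0, r0 = dom
            rz = ry = rx = r0
        else:
            z0, y0, x0, rz, ry, rx = dom
        if (
            z0 - rz < 0
            or z0 + rz > nz * params.fish_slice_um
            or y0 - ry < 0
            or y0 + ry > ny * params.fish_pixel_um
            or x0 - rx < 0
            or x0 + rx > nx * params.fish_pixel_um
        ):
            raise ValueError("ellipsoid extends beyond stack bounds")
        dz = (zc - z0)[:, None, None] / rz
        dy = (yc - y0)[None, :, None] / ry
        dx = (xc - x0)[None, None, :] / rx
        inside = dz**2 + dy**2 + dx**2 <= 1.0
        stack[inside] = params.fish_signal
        volumes.append(4.0 / 3.0 * np.pi * rz * ry * rx)
    sidecar = {
        "pixel_um": params.fish_pixel_um,
        "slice_um": params.fish_slice_um,
        "analytic_volumes_um3": volumes,
    }
    return stack, sidecar
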