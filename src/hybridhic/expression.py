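"""Differential-expression classification and subgenome-resolved integration.

The per-gene statistics (log2 fold change, FDR) are consumed as inputs —
the count-level model that produced them is upstream of this package.
What lives here is the bespoke integration: threshold classification,
RPKM, TSS-based assignment of genes to Hi-C bins, class-wise
distribution comparisons with Wilcoxon-Mann-Whitney rank tests, and the
marked-vs-unmarked variance contrast with a permutation p-value.

The fold-change wording in the source protocol ("fold change of log2
fold greater than 2") is ambiguous between |log2FC| > 2 and fold > 2
(|log2FC| > 1); the threshold is therefore an explicit required
parameter, ``min_abs_log2fc``, with no silent default in the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 20


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Wilcoxon-Mann-Whitney p-value for x vs y.

    Exact enumeration when both groups have <= 20 observations and the
    data are tie-free, otherwise the normal approximation with
    continuity correction; ties are handled by midranks.
    ``alternative="greater"`` tests whether x is stochastically greater.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def classify_de(
    genes: pd.DataFrame,
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Attach a de_class column: up / down / unchanged / unclassifiable.

    up: fdr < fdr_max and log2fc > +min_abs_log2fc;
    down: fdr < fdr_max and log2fc < -min_abs_log2fc; else unchanged.
    Genes missing either statistic are flagged unclassifiable and the
    count is recorded in ``genes.attrs["n_unclassifiable"]``.
    """
    out = genes.copy()
    fdr = out["fdr"].to_numpy(dtype=float)
    lfc = out["log2fc"].to_numpy(dtype=float)
    missing = np.isnan(fdr) | np.isnan(lfc)
    cls = np.full(len(out), "unchanged", dtype=object)
    sig = ~missing & (fdr < fdr_max)
    cls[sig & (lfc > min_abs_log2fc)] = "up"
    cls[sig & (lfc < -min_abs_log2fc)] = "down"
    cls[missing] = "unclassifiable"
    out["de_class"] = cls
    out.attrs["n_unclassifiable"] = int(missing.sum())
    return out


def rpkm(count: float, gene_length: int, library_size: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (gene_length / 1_000.0) / (library_size / 1e6)


def add_rpkm(genes: pd.DataFrame) -> pd.DataFrame:
    """RPKM columns for parent and hybrid counts (per-table library sizes)."""
    out = genes.copy()
    lengths = (out["end"] - out["start"]).to_numpy()
    for side in ("parent", "hybrid"):
        lib = float(out[f"{side}_count"].sum())
        out[f"rpkm_{side}"] = [
            rpkm(c, l, lib)
            for c, l in zip(out[f"{side}_count"].to_numpy(), lengths)
        ]
    return out


def assign_genes_to_bins(
    genes: pd.DataFrame,
    resolution: int = 5_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.Series:
    """Bin index of each gene's TSS: floor(TSS / resolution).

    The TSS is ``start`` on the plus strand and ``end`` on the minus
    strand (0-based half-open, so a minus-strand gene ending exactly at
    a bin boundary lands in the next bin).  A TSS beyond the chromosome
    end is rejected; a TSS exactly at the chromosome end is clamped to
    the last bin.
    """
    tss = np.where(
        genes["strand"].to_numpy() == "+",
        genes["start"].to_numpy(),
        genes["end"].to_numpy(),
    )
    bins = tss // resolution
    if chrom_lengths is not None:
        for k, (_, g) in enumerate(genes.iterrows()):
            length = chrom_lengths[g["chrom"]]
            if tss[k] > length:
                raise ValueError(
                    f"gene {g.get('gene_id', '?')!r}: TSS outside chromosome"
                )
            n_bins = -(-length // resolution)
            bins[k] = min(bins[k], n_bins - 1)
    return pd.Series(bins, index=genes.index, name="bin")


def expression_by_class(
    genes: pd.DataFrame,
    class_map: pd.Series | dict,
    value: str = "log2fc",
    alternative: str = "two-sided",
    background: bool = False,
) -> dict:
    """Per-class distribution summaries plus pairwise rank tests.

    ``class_map`` maps gene_id to a class label; ``value`` is either
    ``log2fc`` or ``rpkm_ratio`` (log2 of hybrid over parent RPKM).
    Classes with fewer than 2 members are excluded (with a warning
    entry).  With ``background=True`` an extra class of all genes is
    included.
    """
    if isinstance(class_map, dict):
        class_map = pd.Series(class_map)
    if value == "log2fc":
        vals = genes.set_index("gene_id")["log2fc"]
    elif value == "rpkm_ratio":
        g = add_rpkm(genes).set_index("gene_id")
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(g["rpkm_hybrid"] / g["rpkm_parent"])
        vals = vals.replace([np.inf, -np.inf], np.nan)
    else:
        raise ValueError(f"unknown value kind {value!r}")

    groups: dict[str, np.ndarray] = {}
    excluded = []
    for label in pd.unique(class_map):
        ids = class_map.index[class_map == label]
        v = vals.reindex(ids).dropna().to_numpy()
        if v.size < 2:
            excluded.append(str(label))
            continue
        groups[str(label)] = v
    if background:
        groups["background"] = vals.dropna().to_numpy()
    if len(groups) < 2:
        raise ValueError("need at least 2 classes with >= 2 members")

    summaries = {
        label: {
            "n": int(v.size),
            "median": float(np.median(v)),
            "variance": float(np.var(v, ddof=1)),
        }
        for label, v in groups.items()
    }
    tests = {}
    labels = list(groups)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            tests[f"{a} vs {b}"] = rank_sum_test(
                groups[a], groups[b], alternative=alternative
            )
    return {"summaries": summaries, "tests": tests, "excluded": excluded}


def variance_contrast(
    genes: pd.DataFrame,
    marked: set,
    unmarked: set,
    value: str = "log2fc",
    n_permutations: int = 1_000,
    seed: int = 0,
) -> dict:
    """Variance of log2(hybrid/parent) in marked vs unmarked genes.

    Reports both sample variances, their ratio (marked over unmarked)
    and a one-sided permutation p-value (label shuffling, seeded) for
    variance inflation in the marked set.  Genes with undefined ratios
    are excluded and counted.
    """
    if len(marked) < 10 or len(unmarked) < 10:
        raise ValueError("both gene sets need at least 10 members")
    vals = genes.set_index("gene_id")[value]
    vm = vals.reindex(sorted(marked)).to_numpy(dtype=float)
    vu = vals.reindex(sorted(unmarked)).to_numpy(dtype=float)
    n_excluded = int(np.isnan(vm).sum() + np.isnan(vu).sum())
    vm, vu = vm[~np.isnan(vm)], vu[~np.isnan(vu)]
    if vm.size < 10 or vu.size < 10:
        raise ValueError("fewer than 10 defined ratios per set")
    var_m = float(np.var(vm, ddof=1))
    var_u = float(np.var(vu, ddof=1))
    observed = var_m / var_u
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([vm, vu])
    n_m = vm.size
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        r = np.var(pooled[:n_m], ddof=1) / np.var(pooled[n_m:], ddof=1)
        if r >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return {
        "var_marked": var_m,
        "var_unmarked": var_u,
        "ratio": observed,
        "p_permutation": p,
        "n_excluded": n_excluded,
    }
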