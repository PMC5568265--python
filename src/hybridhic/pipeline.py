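"""Configuration-driven end-to-end analysis on synthetic hybrid data.

``run_pipeline`` simulates a parent and a hybrid genotype over one
shared genome layout, then runs the full chain: pair binning, masking,
iterative balancing (eps 1e-4; genome-wide at 20 kb, per-chromosome at
5 kb), reference-lag scaling, compactness and compactness ratios with
top/bottom quantile classes, windowed decay exponents, chromosome decay
curves, methylation profiles with cutoff grouping, the H3K27me3/H3
ratio track, gene marking and concordance, subgenome-resolved expression
tests, and FISH stack volumetry.  It writes all intermediates as plain
text, a JSON manifest (parameters, seed, file checksums) and a JSON
report.  Identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .compaction import (
    bin_compactness,
    chromosome_decay_curve,
    compactness_ratio,
    decay_exponent_track,
)
from .contacts import bin_contacts, ice_normalize, mask_low_coverage
from .expression import (
    classify_de,
    expression_by_class,
    rank_sum_test,
    variance_contrast,
)
from .fish import ZStack, compare_volumes, stack_volume
from .marks import (
    call_peaks_simple,
    coverage_ratio_track,
    mark_genes_by_peaks,
    marked_set_concordance,
)
from .methylation import chromosome_profile, split_bins_by_cutoff
from .simulate import (
    SimulationParams,
    make_genome_layout,
    simulate_contact_pairs,
    simulate_fish_stack,
    simulate_marks_and_expression,
    simulate_methylome,
)

# every protocol-level parameter appears as a named key; values the
# protocol fixes are defaulted to it, free parameters have no default
DEFAULT_CONFIG = {
    "resolution_fine": 5_000,
    "resolution_coarse": 20_000,
    "ice_eps": 1e-4,
    "ice_max_iter": 200,
    "mask_quantile": 0.01,
    "decay_window": 100_000,
    "meth_bin": 50_000,
    "chip_window": 100,
    "mark_min_fraction": 0.5,
    "fdr_max": 0.05,
    "compactness_quantile": 0.10,
    "fish_threshold": 25.0,
    "fish_slice_um": 0.22,
    "fish_pixel_um": 0.05,
    "chh_cutoff": 0.10,
    "peak_ratio_threshold": 2.0,
    "n_pairs": 400_000,
    "hybrid_compaction_shift": 0.15,
    "n_fish_nuclei": 6,
    "fish_radius_parent_um": 2.0,
    "fish_radius_hybrid_um": 1.6,
    "chrom_length_a": 1_500_000,
    "chrom_length_b": 1_500_000,
}
REQUIRED_KEYS = ("seed", "min_abs_log2fc")


def validate_config(config: dict) -> dict:
    """Fill defaults; reject unknown keys and missing required keys."""
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    unknown = set(config) - set(DEFAULT_CONFIG) - set(REQUIRED_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    full = dict(DEFAULT_CONFIG)
    full.update(config)
    if not isinstance(full["seed"], (int, np.integer)):
        raise ValueError("seed must be an integer")
    return full


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _balanced_scaled(pairs, layout, resolution, cfg, unit):
    m = bin_contacts(pairs, layout, resolution)
    m = mask_low_coverage(m, quantile=cfg["mask_quantile"], layout=layout)
    bal, bias = ice_normalize(
        m, eps=cfg["ice_eps"], max_iter=cfg["ice_max_iter"], unit=unit
    )
    return bal, bias


def run_pipeline(config: dict, outdir) -> dict:
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed}
    manifest: dict = {"config": {k: cfg[k] for k in sorted(cfg)}, "outputs": {}}
    stage = "init"
    try:
        # ---- simulate ----------------------------------------------------
        stage = "simulate"
        base = SimulationParams(
            seed=seed,
            resolution=cfg["resolution_fine"],
            n_pairs=int(cfg["n_pairs"]),
            chrom_length_a=int(cfg["chrom_length_a"]),
            chrom_length_b=int(cfg["chrom_length_b"]),
            chip_window=int(cfg["chip_window"]),
        )
        layout = make_genome_layout(base)
        shift = cfg["hybrid_compaction_shift"]
        parent_params = base
        hybrid_params = replace(
            base,
            seed=seed + 1,
            alpha_overrides={
                ("A", "arm"): base.alpha_arm + shift,
                ("A", "pericentromere"): base.alpha_pericentromere + shift,
            },
        )
        pairs = {}
        for geno, prm in (("parent", parent_params), ("hybrid", hybrid_params)):
            p, side = simulate_contact_pairs(layout, prm)
            pairs[geno] = p
            io.write_pairs(p, outdir / f"pairs_{geno}.tsv")
            side["bias"].to_csv(
                outdir / f"truth_bias_{geno}.tsv", sep="\t", index=False
            )
            side["alpha"].to_csv(
                outdir / f"truth_alpha_{geno}.tsv", sep="\t", index=False
            )

        # ---- Hi-C: fine maps, compactness, decay -------------------------
        stage = "hic"
        profiles = {}
        decay = {}
        for geno in ("parent", "hybrid"):
            bal, _ = _balanced_scaled(
                pairs[geno], layout, cfg["resolution_fine"], cfg, "chromosome"
            )
            prof = bin_compactness(bal)
            profiles[geno] = prof
            io.write_bedgraph(prof.track, outdir / f"compactness_{geno}.bedgraph")
            dec = decay_exponent_track(bal, window=int(cfg["decay_window"]))
            decay[geno] = dec
            io.write_bedgraph(dec.track, outdir / f"decay_{geno}.bedgraph")

        ratio_track, bottom, top = compactness_ratio(
            profiles["hybrid"], profiles["parent"],
            quantile=cfg["compactness_quantile"],
        )
        io.write_bedgraph(ratio_track, outdir / "compactness_ratio.bedgraph")
        sub_of_bin = np.array(
            [layout.subgenome(c) for c in ratio_track.bins["chrom"]]
        )
        ratio_summary = {}
        for sub in ("A", "B"):
            vals = ratio_track.values[(sub_of_bin == sub) & ratio_track.defined]
            ratio_summary[sub] = {
                "n": int(vals.size),
                "median": float(np.median(vals)) if vals.size else None,
                "fraction_above_1": (
                    float(np.mean(vals > 1)) if vals.size else None
                ),
            }
        report["compactness_ratio"] = ratio_summary
        report["decay_exponent_medians"] = {
            geno: {
                sub: float(
                    np.nanmedian(
                        decay[geno].track.values[
                            np.array(
                                [
                                    layout.subgenome(c) == sub
                                    for c in decay[geno].track.bins["chrom"]
                                ]
                            )
                        ]
                    )
                )
                for sub in ("A", "B")
            }
            for geno in ("parent", "hybrid")
        }

        # ---- Hi-C: coarse maps, chromosome decay curves ------------------
        stage = "decay_curves"
        curves = {}
        for geno in ("parent", "hybrid"):
            bal20, _ = _balanced_scaled(
                pairs[geno], layout, cfg["resolution_coarse"], cfg, "genome"
            )
            curve = chromosome_decay_curve(bal20, max_distance=500_000)
            curve.to_csv(
                outdir / f"decay_curve_{geno}.tsv", sep="\t", index=False
            )
            curves[geno] = curve
        report["decay_curves"] = {
            g: int(len(c)) for g, c in curves.items()
        }

        # ---- methylation --------------------------------------------------
        stage = "methylation"
        calls = simulate_methylome(layout, parent_params)
        io.write_calls(calls, outdir / "methylome.tsv")
        meth_summary = {}
        for ctx in ("CG", "CHG", "CHH"):
            prof = chromosome_profile(
                calls, ctx, bin=int(cfg["meth_bin"]), layout=layout
            )
            io.write_bedgraph(prof, outdir / f"meth_{ctx}.bedgraph")
            meth_summary[ctx] = float(np.nanmean(prof.values))
        report["methylation_means"] = meth_summary

        chh5 = chromosome_profile(
            calls, "CHH", bin=int(cfg["resolution_fine"]), layout=layout
        )
        te5 = _te_at_resolution(layout, int(cfg["resolution_fine"]))
        g1, g2, te_summary = split_bins_by_cutoff(
            chh5, cfg["chh_cutoff"], te5
        )
        report["chh_cutoff_groups"] = te_summary.to_dict(orient="records")

        # ---- marks and expression ----------------------------------------
        stage = "marks"
        me = simulate_marks_and_expression(layout, parent_params)
        genes = me["genes"]
        ratio = coverage_ratio_track(me["k27_parent"], me["h3"])
        io.write_bedgraph(ratio, outdir / "k27_h3_ratio_parent.bedgraph")
        peaks_called = {
            "parent": call_peaks_simple(
                coverage_ratio_track(me["k27_parent"], me["h3"]),
                cfg["peak_ratio_threshold"],
            ),
            "hybrid": call_peaks_simple(
                coverage_ratio_track(me["k27_hybrid"], me["h3"]),
                cfg["peak_ratio_threshold"],
            ),
        }
        marked = {
            g: mark_genes_by_peaks(
                genes, peaks_called[g], min_fraction=cfg["mark_min_fraction"]
            )
            for g in ("parent", "hybrid")
        }
        universe = set(genes["gene_id"])
        conc = marked_set_concordance(
            marked["parent"], marked["hybrid"], universe
        )
        report["mark_concordance"] = conc

        # ---- expression integration --------------------------------------
        stage = "expression"
        genes = classify_de(
            genes,
            fdr_max=cfg["fdr_max"],
            min_abs_log2fc=cfg["min_abs_log2fc"],
        )
        io.write_gene_table(genes, outdir / "genes.tsv")
        report["de_counts"] = (
            genes.groupby(["subgenome", "de_class"]).size().unstack(fill_value=0)
        ).to_dict()

        expr_tests = {}
        for sub in ("A", "B"):
            gsub = genes[genes["subgenome"] == sub]
            both = marked["parent"] & marked["hybrid"] & set(gsub["gene_id"])
            unmarked = (
                set(gsub["gene_id"]) - marked["parent"] - marked["hybrid"]
            )
            vm = gsub.set_index("gene_id")["log2fc"].reindex(sorted(both)).dropna()
            vu = (
                gsub.set_index("gene_id")["log2fc"]
                .reindex(sorted(unmarked))
                .dropna()
            )
            if len(vm) >= 2 and len(vu) >= 2:
                p_less = rank_sum_test(
                    vm.to_numpy(), vu.to_numpy(), alternative="less"
                )
                expr_tests[sub] = {
                    "n_marked": int(len(vm)),
                    "n_unmarked": int(len(vu)),
                    "median_marked": float(vm.median()),
                    "median_unmarked": float(vu.median()),
                    "p_one_sided_down": p_less,
                }
                if len(vm) >= 10 and len(vu) >= 10:
                    expr_tests[sub]["variance_contrast"] = variance_contrast(
                        gsub, set(vm.index), set(vu.index), seed=seed
                    )
        report["marked_expression_tests"] = expr_tests

        # top/bottom compactness-ratio classes vs expression (background too)
        from .expression import assign_genes_to_bins

        lengths = {c: layout.length(c) for c in layout.chrom_names}
        a_genes = genes[genes["subgenome"] == "A"].reset_index(drop=True)
        bins_of = assign_genes_to_bins(
            a_genes, resolution=int(cfg["resolution_fine"]), chrom_lengths=lengths
        )
        chrom_offset = {}
        off = 0
        for c in layout.chrom_names:
            chrom_offset[c] = off
            off += -(-layout.length(c) // int(cfg["resolution_fine"]))
        global_bin = np.array(
            [chrom_offset[c] for c in a_genes["chrom"]]
        ) + bins_of.to_numpy()
        # rank ratios within subgenome A only (the subgenome whose
        # compaction shifts); genome-wide quantiles would be dominated by
        # the A/B offset itself
        a_defined = np.flatnonzero((sub_of_bin == "A") & ratio_track.defined)
        order = a_defined[
            np.argsort(ratio_track.values[a_defined], kind="stable")
        ]
        k = int(np.floor(cfg["compactness_quantile"] * order.size))
        class_map = {}
        bottom_set, top_set = set(order[:k]), set(order[order.size - k :])
        for gid, b in zip(a_genes["gene_id"], global_bin):
            if b in bottom_set:
                class_map[gid] = "bottom10"
            elif b in top_set:
                class_map[gid] = "top10"
        if len(set(class_map.values())) == 2:
            try:
                report["compactness_class_expression"] = expression_by_class(
                    a_genes, class_map, value="log2fc"
                )
            except ValueError as exc:
                report["compactness_class_expression"] = {"note": str(exc)}

        # ---- FISH ---------------------------------------------------------
        stage = "fish"
        vols = {}
        rng = np.random.default_rng((seed, 99))
        for geno, r0 in (
            ("parent", cfg["fish_radius_parent_um"]),
            ("hybrid", cfg["fish_radius_hybrid_um"]),
        ):
            vv = []
            for k in range(int(cfg["n_fish_nuclei"])):
                r = r0 * rng.uniform(0.9, 1.1)
                prm = replace(
                    base,
                    seed=seed + 1000 + k,
                    fish_pixel_um=cfg["fish_pixel_um"],
                    fish_slice_um=cfg["fish_slice_um"],
                    fish_spheres=((4.4, 4.0, 4.0, r),),
                )
                stack, side = simulate_fish_stack(prm)
                zs = ZStack(stack, prm.fish_pixel_um, prm.fish_slice_um)
                res = stack_volume(zs, threshold=cfg["fish_threshold"])
                vv.append(res["total_volume_um3"])
            vols[geno] = vv
        report["fish"] = {
            "volumes": vols,
            "comparison": compare_volumes(vols["parent"], vols["hybrid"]),
        }

    except Exception as exc:  # partial manifest with failed-stage marker
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    # ---- manifest and report ---------------------------------------------
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report


def _te_at_resolution(layout, resolution: int):
    """Resample the layout's TE-density track onto ``resolution`` bins."""
    from .tracks import BinTrack, tile_genome

    bins = tile_genome(layout, resolution)
    mids = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    vals = np.empty(len(bins))
    for chrom in layout.chrom_names:
        sel = (bins["chrom"] == chrom).to_numpy()
        vals[sel] = layout.te_density_at(chrom, mids[sel])
    return BinTrack(bins, vals, resolution, name="te_density")
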