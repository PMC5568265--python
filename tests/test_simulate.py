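"""Synthetic-data generator: layout invariants, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hybridhic as hh


def small_params(**kw):
    defaults = dict(
        seed=1,
        n_chrom_a=2,
        n_chrom_b=2,
        chrom_length_a=300_000,
        chrom_length_b=300_000,
        n_pairs=20_000,
        genes_per_mb=100,
    )
    defaults.update(kw)
    return hh.SimulationParams(**defaults)


class TestGenomeLayout:
    def test_default_chromosome_complement(self):
        layout = hh.make_genome_layout(hh.SimulationParams(seed=1))
        assert len(layout.chrom_names) == 13
        counts = layout.chromosomes["subgenome"].value_counts()
        assert counts["A"] == 5 and counts["B"] == 8
        # the B subgenome continues the numbering as chromosomes 6..13
        assert layout.chroms_of("B")[0] == "chr6"
        assert layout.chroms_of("B")[-1] == "chr13"

    def test_segments_tile_each_chromosome(self):
        layout = hh.make_genome_layout(small_params())
        for chrom in layout.chrom_names:
            seg = layout.segments_of(chrom)
            assert seg["start"].iloc[0] == 0
            assert seg["end"].iloc[-1] == layout.length(chrom)
            assert (seg["start"].to_numpy()[1:] == seg["end"].to_numpy()[:-1]).all()

    def test_degenerate_single_arm_chromosome(self):
        params = hh.SimulationParams(
            seed=1,
            n_chrom_a=1,
            n_chrom_b=0,
            chrom_length_a=1_000_000,
            pericentromere_fraction=0.0,
            masked_fraction=0.0,
        )
        layout = hh.make_genome_layout(params)
        seg = layout.segments_of("chr1")
        assert len(seg) == 1
        assert seg.iloc[0]["label"] == "arm"
        assert (seg.iloc[0]["start"], seg.iloc[0]["end"]) == (0, 1_000_000)

    def test_te_ratio_recovered_from_track(self):
        layout = hh.make_genome_layout(hh.SimulationParams(seed=9, te_ratio=5.0))
        ratio = layout.mean_te_density("B", "arm") / layout.mean_te_density(
            "A", "arm"
        )
        assert ratio == pytest.approx(5.0, abs=0.5)

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chr1"):
            hh.make_genome_layout(
                hh.SimulationParams(seed=1, chrom_length_a=50_000)
            )


class TestDeterminism:
    def test_identical_seed_byte_identical(self):
        outs = []
        for _ in range(2):
            params = small_params(seed=77)
            layout = hh.make_genome_layout(params)
            pairs, sidecar = hh.simulate_contact_pairs(layout, params)
            calls = hh.simulate_methylome(layout, params)
            me = hh.simulate_marks_and_expression(layout, params)
            stack, _ = hh.simulate_fish_stack(params)
            outs.append(
                (
                    pairs.to_csv(),
                    sidecar["bias"].to_csv(),
                    calls.to_csv(),
                    me["genes"].to_csv(),
                    stack.tobytes(),
                )
            )
        assert outs[0] == outs[1]

    def test_different_seed_differs(self):
        p1, p2 = small_params(seed=1), small_params(seed=2)
        layout = hh.make_genome_layout(p1)
        a, _ = hh.simulate_contact_pairs(layout, p1)
        b, _ = hh.simulate_contact_pairs(layout, p2)
        assert not a.equals(b)


class TestContactPairs:
    def test_pair_count_conserved(self):
        params = small_params(n_pairs=12_345)
        layout = hh.make_genome_layout(params)
        pairs, _ = hh.simulate_contact_pairs(layout, params)
        assert len(pairs) == 12_345

    def test_zero_pairs_empty(self):
        params = small_params(n_pairs=0)
        layout = hh.make_genome_layout(params)
        pairs, sidecar = hh.simulate_contact_pairs(layout, params)
        assert len(pairs) == 0
        assert len(sidecar["bias"]) == 0

    def test_no_bias_means_equal_biases(self):
        params = small_params(bias_sd=0.0)
        layout = hh.make_genome_layout(params)
        _, sidecar = hh.simulate_contact_pairs(layout, params)
        b = sidecar["bias"]["bias"].to_numpy()
        assert set(np.unique(b)) <= {0.0, 1.0}  # masked bins carry 0

    def test_trans_rate_emits_trans_pairs(self):
        params = small_params(trans_rate=0.1, n_pairs=10_000)
        layout = hh.make_genome_layout(params)
        pairs, _ = hh.simulate_contact_pairs(layout, params)
        n_trans = (pairs["chrom1"] != pairs["chrom2"]).sum()
        assert n_trans == 1_000
        assert len(pairs) == 10_000

    def test_alpha_recovery_through_pipeline(self):
        # ICE-corrected counts from an alpha = -1 no-bias simulation fit
        # slope -1 in log-log regression over lags 2..10
        params = hh.SimulationParams(
            seed=31,
            n_chrom_a=1,
            n_chrom_b=0,
            chrom_length_a=1_000_000,
            pericentromere_fraction=0.0,
            masked_fraction=0.0,
            bias_sd=0.0,
            n_pairs=2_000_000,
        )
        layout = hh.make_genome_layout(params)
        pairs, _ = hh.simulate_contact_pairs(layout, params)
        m = hh.mask_low_coverage(hh.bin_contacts(pairs, layout, 5_000))
        bal, _ = hh.ice_normalize(m, unit="genome")
        sym = bal.dense()
        lags = np.arange(2, 11)
        means = [np.diag(sym, k).mean() for k in lags]
        slope = np.polyfit(np.log(lags), np.log(means), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)


class TestMethylome:
    def test_zero_rate_all_zero(self):
        params = small_params(
            meth_means={"CG": 0.5, "CHG": 0.2, "CHH": 0.0},
            meth_te_coupling={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
        )
        layout = hh.make_genome_layout(params)
        calls = hh.simulate_methylome(layout, params)
        chh = calls[calls["context"] == "CHH"]
        assert (chh["methylated"] == 0).all()

    def test_global_cg_mean_recovered(self):
        params = small_params(
            meth_means={"CG": 0.9, "CHG": 0.1, "CHH": 0.05},
            meth_te_coupling={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
        )
        layout = hh.make_genome_layout(params)
        calls = hh.simulate_methylome(layout, params)
        cg = calls[calls["context"] == "CG"]
        assert len(cg) >= 1e3
        ratio = cg["methylated"].sum() / cg["total"].sum()
        assert ratio == pytest.approx(0.9, abs=0.02)

    def test_te_coupling_produces_positive_correlation(self):
        params = small_params(seed=5)
        layout = hh.make_genome_layout(params)
        calls = hh.simulate_methylome(layout, params)
        track = hh.chromosome_profile(calls, "CHH", bin=10_000, layout=layout)
        te = layout.te_density
        ok = ~np.isnan(track.values)
        r = stats.pearsonr(track.values[ok], te["value"].to_numpy()[ok])[0]
        assert r > 0.5

    def test_bad_coverage_rejected(self):
        params = small_params(meth_coverage=0)
        layout = hh.make_genome_layout(params)
        with pytest.raises(ValueError):
            hh.simulate_methylome(layout, params)


class TestMarksAndExpression:
    def test_null_model_equal_variances(self):
        params = small_params(
            seed=8, marked_a_shift=0.0, marked_a_extra_sd=0.0, genes_per_mb=400
        )
        layout = hh.make_genome_layout(params)
        me = hh.simulate_marks_and_expression(layout, params)
        g = me["genes"]
        marked = g.loc[g["k27_parent"], "log2fc"]
        unmarked = g.loc[~g["k27_parent"], "log2fc"]
        ratio = marked.var() / unmarked.var()
        assert 0.6 < ratio < 1.6

    def test_marked_fraction_zero_empty_peaks(self):
        params = small_params(marked_fraction=0.0, mark_gain_rate=0.0)
        layout = hh.make_genome_layout(params)
        me = hh.simulate_marks_and_expression(layout, params)
        assert len(me["peaks_parent"]) == 0
        assert len(me["peaks_hybrid"]) == 0

    def test_peaks_cover_more_than_half_of_marked_genes(self):
        params = small_params(seed=3)
        layout = hh.make_genome_layout(params)
        me = hh.simulate_marks_and_expression(layout, params)
        marked = hh.mark_genes_by_peaks(me["genes"], me["peaks_parent"])
        assert marked == me["truth"]["marked_parent"]

    def test_invalid_fraction_rejected(self):
        params = small_params(marked_fraction=1.5)
        layout = hh.make_genome_layout(params)
        with pytest.raises(ValueError):
            hh.simulate_marks_and_expression(layout, params)

    def test_shift_detected_downstream(self):
        # -0.5 log2 shift on A-subgenome marked genes: the one-sided rank
        # test finds it; the B subgenome stays null
        params = hh.SimulationParams(
            seed=12,
            n_chrom_a=3,
            n_chrom_b=3,
            chrom_length_a=2_000_000,
            chrom_length_b=2_000_000,
            genes_per_mb=200,
            marked_a_shift=-0.5,
        )
        layout = hh.make_genome_layout(params)
        me = hh.simulate_marks_and_expression(layout, params)
        g = me["genes"]
        assert len(g) >= 2_000
        for sub, expect_shift in (("A", True), ("B", False)):
            gs = g[g["subgenome"] == sub]
            both = gs["k27_parent"] & gs["k27_hybrid"]
            p = hh.rank_sum_test(
                gs.loc[both, "log2fc"],
                gs.loc[~gs["k27_parent"] & ~gs["k27_hybrid"], "log2fc"],
                alternative="less",
            )
            if expect_shift:
                assert p < 0.01
            else:
                assert p > 0.05


class TestFishSidecar:
    def test_blank_stack_below_threshold(self):
        params = small_params(fish_spheres=())
        stack, sidecar = hh.simulate_fish_stack(params)
        assert (stack <= 25).all()
        assert sidecar["analytic_volumes_um3"] == []

    def test_sphere_analytic_volume(self):
        params = small_params()  # default r = 2 um sphere
        _, sidecar = hh.simulate_fish_stack(params)
        assert sidecar["analytic_volumes_um3"][0] == pytest.approx(
            33.51, abs=0.01
        )

    def test_two_domains_listed(self):
        params = small_params(
            fish_spheres=((2.2, 2.0, 2.0, 1.0), (6.0, 6.0, 6.0, 1.0))
        )
        _, sidecar = hh.simulate_fish_stack(params)
        assert len(sidecar["analytic_volumes_um3"]) == 2

    def test_out_of_bounds_rejected(self):
        params = small_params(fish_spheres=((0.1, 4.0, 4.0, 2.0),))
        with pytest.raises(ValueError, match="bounds"):
            hh.simulate_fish_stack(params)


class TestParamsValidation:
    def test_positive_alpha_rejected(self):
        with pytest.raises(ValueError):
            hh.SimulationParams(seed=1, alpha_arm=0.5)

    def test_seed_required(self):
        with pytest.raises(TypeError):
            hh.SimulationParams()  # no seed
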