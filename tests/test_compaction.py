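"""Compactness statistic, decay exponents, decay curves, region aggregates."""

import numpy as np
import pandas as pd
import pytest

import hybridhic as hh
from hybridhic.compaction import CompactnessProfile
from helpers import (
    decay_slope_oracle,
    dense_to_matrix,
    power_law_matrix,
    track_from_values,
)

# 2 * sum_{k=2..10} 1/k, the interior compactness of an exact 1/d map
K_POWER_LAW = 2 * sum(1.0 / k for k in range(2, 11))


def profile_from_values(values):
    track = track_from_values(values)
    return CompactnessProfile(track, np.full(len(track), 18))


class TestBinCompactness:
    def test_constant_matrix_interior_K_is_18(self):
        n = 30
        dense = np.ones((n, n))
        m = dense_to_matrix(dense, state="scaled")
        prof = hh.bin_compactness(m)
        interior = slice(10, n - 10)
        assert np.allclose(prof.values[interior], 18.0)

    def test_power_law_interior_K(self):
        m = power_law_matrix(40, -1.0)
        prof = hh.bin_compactness(m)
        interior = slice(10, 30)
        assert np.allclose(prof.values[interior], K_POWER_LAW, atol=1e-6)
        assert K_POWER_LAW == pytest.approx(3.8580, abs=1e-4)

    def test_mostly_masked_neighbourhood_undefined(self):
        n = 30
        mask = np.zeros(n, dtype=bool)
        mask[5:20] = True  # bin 15 of bin 12's 18 neighbours masked
        mask[12] = False
        m = dense_to_matrix(np.ones((n, n)), state="scaled", mask=mask)
        prof = hh.bin_compactness(m)
        assert np.isnan(prof.values[12])

    def test_internal_lag1_scaling_makes_K_depth_invariant(self):
        m1 = power_law_matrix(40, -1.0, state="balanced")
        m2 = power_law_matrix(40, -1.0, state="balanced")
        m2.values = m2.values * 7.5  # same map at 7.5x depth
        k1 = hh.bin_compactness(m1).values
        k2 = hh.bin_compactness(m2).values
        assert np.allclose(k1, k2, equal_nan=True)

    def test_wrong_resolution_rejected(self):
        m = power_law_matrix(40, -1.0, resolution=10_000)
        with pytest.raises(ValueError, match="5-kb"):
            hh.bin_compactness(m)
        prof = hh.bin_compactness(m, any_resolution=True)
        assert prof.values.shape == (40,)

    def test_shallower_decay_means_higher_K(self):
        k_shallow = hh.bin_compactness(power_law_matrix(60, -0.6)).values
        k_steep = hh.bin_compactness(power_law_matrix(60, -1.2)).values
        ok = ~np.isnan(k_shallow)
        assert np.all(k_shallow[ok] > k_steep[ok])


class TestCompactnessRatio:
    def test_identity(self):
        p = profile_from_values(np.linspace(1, 2, 20))
        track, bottom, top = hh.compactness_ratio(p, p)
        assert np.allclose(track.values, 1.0)
        assert len(bottom) == len(top) == 2

    def test_quantile_arithmetic(self):
        vals = [0.5, 1, 1, 2, 4, 8, 9, 10, 11, 12]
        num = profile_from_values(vals)
        den = profile_from_values(np.ones(10))
        track, bottom, top = hh.compactness_ratio(num, den, quantile=0.1)
        assert list(track.values[bottom]) == [0.5]
        assert list(track.values[top]) == [12]

    def test_zero_denominator_undefined(self):
        num = profile_from_values([1.0, 2.0, 3.0])
        den = profile_from_values([1.0, 0.0, 1.0])
        track, _, _ = hh.compactness_ratio(num, den)
        assert np.isnan(track.values[1])

    def test_bin_mismatch_rejected(self):
        a = profile_from_values(np.ones(5))
        b = profile_from_values(np.ones(6))
        with pytest.raises(ValueError):
            hh.compactness_ratio(a, b)


class TestDecayExponent:
    def test_exact_power_law_slope(self):
        m = power_law_matrix(40, -1.2)
        dec = hh.decay_exponent_track(m, window=100_000)  # 20-bin windows
        assert np.allclose(dec.track.values, -1.2, atol=1e-9)

    def test_constant_matrix_slope_zero(self):
        m = dense_to_matrix(np.ones((40, 40)), state="balanced")
        dec = hh.decay_exponent_track(m, window=100_000)
        assert np.allclose(dec.track.values, 0.0, atol=1e-12)

    def test_fewer_than_six_lag_means_no_value(self):
        # 6-bin windows only reach lag 5 -> five means -> undefined
        m = power_law_matrix(12, -1.0)
        dec = hh.decay_exponent_track(m, window=30_000)
        assert np.all(np.isnan(dec.track.values))
        assert np.all(dec.n_lags <= 5)

    def test_window_not_multiple_rejected(self):
        m = power_law_matrix(40, -1.0)
        with pytest.raises(ValueError):
            hh.decay_exponent_track(m, window=99_999)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            n = 30
            dense = rng.uniform(0.1, 5.0, size=(n, n))
            dense = (dense + dense.T) / 2
            mask = rng.random(n) < 0.15
            m = dense_to_matrix(dense, state="balanced", mask=mask)
            m.values = m.values.multiply(
                np.outer(~mask, ~mask)
            ).tocsr()
            dec = hh.decay_exponent_track(m, window=75_000)  # 15-bin windows
            sym = m.dense()
            for w_idx, w0 in enumerate(range(0, n - 15 + 1, 15)):
                expected, _ = decay_slope_oracle(sym, mask, w0, w0 + 15, 5_000)
                got = dec.track.values[w_idx]
                if expected is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-9)


class TestDecayCurve:
    def test_reference_distance_is_one(self):
        rng = np.random.default_rng(3)
        dense = rng.uniform(0.5, 2.0, size=(30, 30))
        dense = dense + dense.T
        m = dense_to_matrix(dense, resolution=20_000, state="balanced")
        curve = hh.chromosome_decay_curve(m)
        assert curve.loc[curve["distance"] == 20_000, "rel_frequency"].iloc[
            0
        ] == pytest.approx(1.0)

    def test_alpha_minus_one_halves_at_double_distance(self):
        m = power_law_matrix(30, -1.0, resolution=20_000)
        curve = hh.chromosome_decay_curve(m)
        at40 = curve.loc[curve["distance"] == 40_000, "rel_frequency"].iloc[0]
        assert at40 == pytest.approx(0.5, abs=1e-12)

    def test_monotone_decay_curve_non_increasing(self):
        m = power_law_matrix(40, -0.8, resolution=20_000)
        curve = hh.chromosome_decay_curve(m, max_distance=400_000)
        vals = curve["rel_frequency"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-12)


class TestRegionAggregates:
    def regions(self, *spans):
        return pd.DataFrame(
            [("chr1", s, e) for s, e in spans], columns=["chrom", "start", "end"]
        )

    def test_constant_field(self):
        m = dense_to_matrix(np.full((10, 10), 2.5), state="balanced")
        res = hh.aggregate_region_interactions(
            m, self.regions((0, 10_000)), self.regions((30_000, 50_000))
        )
        assert res["mean"] == pytest.approx(2.5)

    def test_hand_enumerated_pairs(self):
        dense = np.zeros((6, 6))
        vals = {(0, 4): 1.0, (0, 5): 2.0, (1, 4): 3.0, (1, 5): 4.0}
        for (i, j), v in vals.items():
            dense[i, j] = dense[j, i] = v
        m = dense_to_matrix(dense, state="balanced")
        res = hh.aggregate_region_interactions(
            m, self.regions((0, 10_000)), self.regions((20_000, 30_000))
        )
        assert res["n"] == 4
        assert res["mean"] == pytest.approx(2.5)

    def test_self_pair_excluded(self):
        m = dense_to_matrix(np.ones((6, 6)), state="balanced")
        one_bin = self.regions((0, 5_000))
        res = hh.aggregate_region_interactions(m, one_bin, one_bin, scope="cis")
        assert res["mean"] is None
        assert res["n"] == 0

    def test_empty_region_set_rejected(self):
        m = dense_to_matrix(np.ones((6, 6)), state="balanced")
        with pytest.raises(ValueError):
            hh.aggregate_region_interactions(
                m, self.regions(), self.regions((0, 5_000))
            )

    def test_flanking_contrast(self):
        dense = np.ones((12, 12))
        m = dense_to_matrix(dense, state="balanced")
        res = hh.aggregate_region_interactions(
            m,
            self.regions((20_000, 30_000)),
            self.regions((40_000, 50_000)),
            flank=10_000,
        )
        assert res["flank_mean"] == pytest.approx(1.0)
        assert res["flank_n"] > 0
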