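"""Estuary-scale statistics: hypsometry, trends, binned surfaces, the flag."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tidalmarsh import (
    GridRaster,
    YearPair,
    annual_trend,
    early_indicator_report,
    establishment_array,
    hypsometric_curve,
    intensity_by_slope,
    slope_deg,
    slope_hypsometry,
)
from tidalmarsh.errors import InsufficientDataError, InvalidArgumentError


def _exp(values):
    return GridRaster(np.asarray(values, dtype=float), "skipped_pct", 10.0)


class TestHypsometry:
    def test_uniform_value_step(self):
        c = hypsometric_curve(_exp(np.full((10, 10), 20.0)))
        assert c.evaluate(10.0) == 100.0
        assert c.evaluate(20.0) == 100.0
        assert c.evaluate(20.1) == 0.0

    def test_non_increasing(self, rng):
        c = hypsometric_curve(_exp(rng.uniform(0, 100, (30, 30))))
        grid = np.linspace(0, 100, 50)
        vals = c.evaluate(grid)
        assert np.all(np.diff(vals) <= 0)
        assert c.evaluate(0.0) == 100.0

    def test_uniform_distribution_matches_line(self, rng):
        vals = rng.uniform(0, 100, 100_000)
        c = hypsometric_curve(_exp(vals.reshape(250, 400)))
        grid = np.linspace(1, 99, 25)
        assert np.all(np.abs(c.evaluate(grid) - (100 - grid)) < 2.0)

    def test_permutation_invariance(self, rng):
        vals = rng.uniform(0, 100, 400)
        a = hypsometric_curve(_exp(vals.reshape(20, 20)))
        b = hypsometric_curve(_exp(rng.permutation(vals).reshape(20, 20)))
        grid = np.linspace(0, 100, 31)
        assert np.array_equal(a.evaluate(grid), b.evaluate(grid))

    def test_no_valid_cells_rejected(self):
        with pytest.raises(InsufficientDataError):
            hypsometric_curve(_exp(np.zeros((5, 5))))


class TestSlopeHypsometry:
    def test_single_bin_equals_plain_hypsometry(self, rng):
        slope = GridRaster(rng.uniform(0, 2, (20, 20)), "slope", 10.0)
        exposure = _exp(rng.uniform(1, 99, (20, 20)))
        out = slope_hypsometry(slope, exposure, np.array([0.0, 100.0]))
        plain = hypsometric_curve(GridRaster(slope.values, "skipped_pct", 10.0))
        grid = np.linspace(0, 2, 21)
        assert np.allclose(out[(0.0, 100.0)].evaluate(grid), plain.evaluate(grid))

    def test_constant_slope_identical_curves(self, rng):
        slope = GridRaster(np.full((20, 20), 0.5), "slope", 10.0)
        exposure = _exp(rng.uniform(1, 99, (20, 20)))
        out = slope_hypsometry(slope, exposure, np.array([0.0, 50.0, 100.0]))
        grid = np.linspace(0, 1, 11)
        curves = list(out.values())
        assert len(curves) == 2
        assert np.array_equal(curves[0].evaluate(grid), curves[1].evaluate(grid))

    def test_convex_flat_is_flatter_higher_up(self, default_scene):
        """Cells higher in the tidal frame have gentler slopes."""
        y = default_scene.config.years[-1]
        slope = slope_deg(default_scene.dems_10m[y])
        exposure = default_scene.exposure_10m[y]
        out = slope_hypsometry(slope, exposure, np.array([0.0, 30.0, 100.0]))
        low, high = out[(0.0, 30.0)], out[(30.0, 100.0)]
        assert np.median(high.values) < np.median(low.values)


class TestAnnualTrend:
    def test_exact_line(self):
        t = annual_trend([(y, 2.0 * y + 5.0) for y in range(2004, 2010)])
        assert t.slope == pytest.approx(2.0, abs=1e-9)
        assert t.stderr == pytest.approx(0.0, abs=1e-9)

    def test_constant_series(self):
        t = annual_trend([(y, 7.0) for y in range(2004, 2009)])
        assert t.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_years_rejected(self):
        with pytest.raises(InvalidArgumentError):
            annual_trend([(2004, 1.0)])
        with pytest.raises(InvalidArgumentError):
            annual_trend([(2004, 1.0), (2004, 2.0)])

    def test_ci_covers_true_slope(self, rng):
        """95% CI covers the true accretion rate in >= 90 of 100 replicates."""
        true = 2.0
        hits = 0
        for _ in range(100):
            years = np.arange(10)
            vals = true * years + rng.normal(0, 0.5, 10)
            t = annual_trend(list(zip(years, vals)))
            hits += t.ci_low <= true <= t.ci_high
        assert hits >= 90


class TestIntensityBySlope:
    def test_constant_intensity_flat_curve(self, rng):
        inten = GridRaster(np.full((30, 30), 0.02), "intensity", 10.0)
        slope = GridRaster(rng.uniform(0.02, 5, (30, 30)), "slope", 10.0)
        out = intensity_by_slope(inten, slope)
        assert np.allclose(out.mean_intensity, 0.02)

    def test_empty_bins_absent(self, rng):
        inten = GridRaster(rng.uniform(0, 1, (10, 10)), "intensity", 10.0)
        slope = GridRaster(np.full((10, 10), 0.1), "slope", 10.0)
        out = intensity_by_slope(inten, slope)
        assert len(out) == 1  # all cells in one bin; others absent, not zero

    def test_all_masked_rejected(self):
        nanr = GridRaster(np.full((5, 5), np.nan), "intensity", 10.0)
        with pytest.raises(InsufficientDataError):
            intensity_by_slope(nanr, nanr)


class TestEstablishmentArray:
    def _pair(self, n_cells, k_new, skipped, inten, rng):
        shape = (1, n_cells)
        new = np.zeros(shape)
        new[0, :k_new] = 1.0
        mk = lambda v, kind: GridRaster(np.full(shape, v) if np.isscalar(v) else v, kind, 10.0)
        return YearPair(
            new_veg=GridRaster(new, "boolean", 10.0),
            at_risk=mk(1.0, "boolean"),
            exposure=mk(skipped, "skipped_pct"),
            intensity=mk(inten, "intensity"),
        )

    def test_direct_proportion(self, rng):
        arr = establishment_array([self._pair(50, 5, 40.2, 0.01, rng)],
                                  intensity_edges=np.linspace(0, 0.1, 86))
        frame = arr.to_frame()
        assert len(frame) == 1
        assert frame.p.iloc[0] == pytest.approx(0.1)
        assert frame.n.iloc[0] == 50

    def test_small_bins_missing_not_zero(self, rng):
        arr = establishment_array([self._pair(29, 3, 40.2, 0.01, rng)],
                                  intensity_edges=np.linspace(0, 0.1, 86))
        assert len(arr.to_frame()) == 0
        assert np.all(np.isnan(arr.probability[arr.n > 0]))

    def test_pooling_equals_concatenation(self, rng):
        p1 = self._pair(40, 4, 40.2, 0.01, rng)
        p2 = self._pair(60, 30, 40.2, 0.01, rng)
        edges = np.linspace(0, 0.1, 86)
        pooled = establishment_array([p1, p2], intensity_edges=edges)
        # counts sum across pairs: p = (4+30)/(40+60), not mean(0.1, 0.5)
        assert pooled.probability[np.nonzero(pooled.n)][0] == pytest.approx(0.34)
        assert pooled.probability_pair_mean[np.nonzero(pooled.n)][0] == pytest.approx(0.3)

    def test_zero_skipped_bin_is_degenerate(self, rng):
        """The first skipped bin holds exactly the 0% class."""
        pair = self._pair(100, 0, 0.0, 0.01, rng)
        pair2 = self._pair(100, 10, 0.4, 0.01, rng)  # just above NHWL
        arr = establishment_array([pair, pair2],
                                  intensity_edges=np.linspace(0, 0.1, 86))
        frame = arr.to_frame()
        zero_rows = frame[frame.skipped_high == 0.0]
        above_rows = frame[frame.skipped_high > 0.0]
        assert len(zero_rows) == 1 and zero_rows.n.iloc[0] == 100
        assert len(above_rows) == 1 and above_rows.p.iloc[0] == pytest.approx(0.1)

    def test_no_pairs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            establishment_array([])


class TestEarlyIndicator:
    def _series(self, base_elev, rate, slope_grad_cm_per_m, years, curve_min=110.0):
        """Tiny flat unit: ramped elevation, exposure thresholded at curve_min."""
        ny, nx = 8, 8
        dems, exps, slopes = [], [], []
        for i, _y in enumerate(years):
            z = (base_elev + rate * i
                 - slope_grad_cm_per_m * 10.0 * np.arange(ny)[:, None]
                 + np.zeros((ny, nx)))
            dem = GridRaster(z, "elevation", 10.0)
            exp = GridRaster(np.clip((z - curve_min) * 2.0, 0.0, 100.0),
                             "skipped_pct", 10.0)
            dems.append(dem)
            exps.append(exp)
            slopes.append(slope_deg(dem))
        return dems, exps, slopes

    def test_accreting_low_slope_flat_flagged(self):
        years = list(range(5))
        dems, exps, slopes = self._series(130.0, 2.5, 0.02, years)
        rep = early_indicator_report(years, dems, exps, slopes)
        assert rep.flagged
        assert rep.accretion.slope == pytest.approx(2.5, abs=1e-6)

    def test_static_steep_flat_not_flagged(self):
        years = list(range(5))
        dems, exps, slopes = self._series(200.0, 0.0, 1.75, years)
        rep = early_indicator_report(years, dems, exps, slopes)
        assert not rep.flagged
        assert rep.mean_slope_deg > 0.3

    def test_below_nhwl_not_flagged(self):
        years = list(range(5))
        dems, exps, slopes = self._series(-50.0, 2.5, 0.02, years)
        rep = early_indicator_report(years, dems, exps, slopes)
        assert not rep.flagged and not rep.above_nhwl

    def test_requires_three_years(self):
        years = [0, 1]
        dems, exps, slopes = self._series(130.0, 2.5, 0.02, years)
        with pytest.raises(InvalidArgumentError):
            early_indicator_report(years, dems, exps, slopes)


@given(st.integers(0, 2**16))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_hypsometry_evaluates_between_0_and_100(seed):
    r = np.random.default_rng(seed)
    c = hypsometric_curve(_exp(r.uniform(0, 100, (10, 10)) + 1e-9))
    vals = c.evaluate(np.linspace(-10, 110, 23))
    assert np.all((vals >= 0) & (vals <= 100))
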