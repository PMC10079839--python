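"""Synthetic estuary generator: construction invariants and truth recovery."""

import numpy as np
import pytest

from tidalmarsh import (
    GridRaster,
    SynthConfig,
    block_resample,
    evolve_vegetation,
    gen_dem_series,
    gen_ortho,
    gen_tide_series,
    generate_scene,
    ndvi,
    slope_deg,
)
from tidalmarsh.errors import InvalidConfigError

M2_H = 12.42


class TestConfigValidation:
    def test_relief_envelope(self):
        with pytest.raises(InvalidConfigError):
            SynthConfig(pattern_relief_cm=12.0)

    def test_years_strictly_increasing(self):
        with pytest.raises(InvalidConfigError):
            SynthConfig(years=(2004, 2004, 2006))

    def test_positive_amplitudes(self):
        with pytest.raises(InvalidConfigError):
            SynthConfig(m2_amplitude_cm=-10.0)

    def test_nonpositive_sampling(self):
        with pytest.raises(InvalidConfigError):
            SynthConfig(tide_sampling_min=0.0)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SynthConfig(seed=3, years=(2004, 2006))
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SynthConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestTides:
    def test_pure_m2_maximum(self):
        cfg = SynthConfig(m2_amplitude_cm=200.0, s2_amplitude_cm=1e-9,
                          tide_noise_sd_cm=0.0,
                          station_amplification=(1.0, 1.0, 1.0))
        s = gen_tide_series(cfg)[0]
        # the sinusoid extremum is hit to within one sample step
        dt_rad = 2 * np.pi * s.dt_h / M2_H
        assert s.levels_cm.max() == pytest.approx(200.0, abs=200 * dt_rad ** 2)

    def test_constructive_superposition_at_spring(self):
        cfg = SynthConfig(tide_noise_sd_cm=0.0,
                          station_amplification=(1.0, 1.0, 1.0))
        s = gen_tide_series(cfg)[0]
        assert s.levels_cm.max() > cfg.m2_amplitude_cm

    def test_spring_neap_envelope_present(self):
        cfg = SynthConfig(tide_noise_sd_cm=0.0,
                          station_amplification=(1.0, 1.0, 1.0))
        s = gen_tide_series(cfg)[0]
        from tidalmarsh import extract_high_tides

        _, peaks = extract_high_tides(s)
        assert peaks.max() - peaks.min() > 1.5 * cfg.s2_amplitude_cm

    def test_amplification_scales_levels(self):
        cfg = SynthConfig(tide_noise_sd_cm=0.0)
        low, _, high = gen_tide_series(cfg)
        assert high.levels_cm.max() == pytest.approx(
            1.2 * low.levels_cm.max(), rel=1e-9)

    def test_seed_determinism(self):
        cfg = SynthConfig(seed=44)
        a = gen_tide_series(cfg)[0]
        b = gen_tide_series(cfg)[0]
        assert np.array_equal(a.levels_cm, b.levels_cm)


class TestDemSeries:
    def test_uniform_accretion_on_flat(self, small_config):
        dems, truth = gen_dem_series(small_config)
        years = small_config.years
        flat = truth.flat_mask.as_bool()
        d = dems[years[1]].values[flat] - dems[years[0]].values[flat]
        assert d.mean() == pytest.approx(small_config.accretion_cm_yr, abs=0.05)

    def test_pattern_only_below_slope_ceiling(self, small_config):
        from tidalmarsh._rng import substream
        from tidalmarsh.synth import _base_profile, _creek_incision

        dems, truth = gen_dem_series(small_config)
        cfg = small_config
        year = cfg.years[-1]
        base = _base_profile(cfg)
        creek_depth, _ = _creek_incision(cfg, substream(cfg.seed, "creeks"))
        w = np.clip((base - cfg.accretion_zero_elev_cm)
                    / (cfg.accretion_full_elev_cm - cfg.accretion_zero_elev_cm), 0, 1)
        smooth = base + cfg.accretion_cm_yr * (year - cfg.years[0]) * w - creek_depth
        pre_slope = slope_deg(GridRaster(smooth, "elevation", 1.0)).values
        pat = truth.pattern_masks[year].as_bool()
        assert pat.any()
        assert np.all(pre_slope[pat] < cfg.pattern_slope_ceiling_deg)

    def test_creek_walls_detectable_at_2m(self, small_scene):
        """Nearly all 10-m tiles containing creek cells have a 2-m cell > 3 deg."""
        year = small_scene.config.years[0]
        slope2 = slope_deg(block_resample(small_scene.dems[year], 2.0, "mean"))
        steep = GridRaster((np.nan_to_num(slope2.values) > 3.0).astype(float),
                           "boolean", 2.0)
        steep10 = block_resample(steep, 10.0, "max").as_bool()
        creek10 = block_resample(small_scene.truth.creek_mask, 10.0, "max").as_bool()
        ny, nx = steep10.shape
        creek10 = creek10[:ny, :nx]
        assert creek10.any()
        assert steep10[creek10].mean() > 0.9

    def test_seed_determinism(self, small_config):
        a, _ = gen_dem_series(small_config)
        b, _ = gen_dem_series(small_config)
        y = small_config.years[-1]
        assert np.array_equal(a[y].values, b[y].values)


class TestOrtho:
    def test_vegetated_cells_exceed_sediment_ndvi(self, small_scene):
        cfg = small_scene.config
        y = cfg.years[0]
        veg_all = GridRaster(np.ones((cfg.grid_shape[0] // 10,
                                      cfg.grid_shape[1] // 10)), "boolean", 10.0)
        img = gen_ortho(small_scene.dems[y], small_scene.exposure_1m[y],
                        veg_all, cfg, year=y)
        nd = ndvi(img).values
        sediment_mode = (1 - cfg.red_ratio) / (1 + cfg.red_ratio)
        assert np.nanmin(nd) > sediment_mode

    def test_no_noise_flat_bed_zero_intensity(self):
        import dataclasses

        from tidalmarsh import intensity

        cfg = SynthConfig(sensor_noise_sd=0.0)
        flat = GridRaster(np.full((40, 40), 150.0), "elevation")
        exp = GridRaster(np.full((40, 40), 50.0), "skipped_pct")
        noveg = GridRaster(np.zeros((4, 4)), "boolean", 10.0)
        img = gen_ortho(flat, exp, noveg, cfg)
        assert np.allclose(intensity(img).values, 0.0, atol=1e-12)

    def test_patterned_windows_brighter_variance(self, small_scene):
        """Windowed SD of NIR is larger where texture was planted."""
        from tidalmarsh import intensity

        cfg = small_scene.config
        y = cfg.years[-1]
        inten = intensity(small_scene.orthos[y], 10.0).values
        pat10 = block_resample(small_scene.truth.pattern_masks[y], 10.0,
                               "max").as_bool()
        veg10 = small_scene.truth.veg_masks[y].as_bool()
        creek10 = block_resample(small_scene.truth.creek_mask, 10.0, "max").as_bool()
        above = small_scene.exposure_10m[y].values > 5  # clear of the waterline band
        pat = pat10 & ~veg10 & ~creek10 & above
        smooth = ~pat10 & ~veg10 & ~creek10 & above
        assert pat.any() and smooth.any()
        assert inten[pat].mean() > 1.5 * inten[smooth].mean()


class TestVegetationDynamics:
    def _fields(self, skipped, intensity_val, shape=(100, 100)):
        return ({0: GridRaster(np.full(shape, skipped), "skipped_pct", 10.0),
                 1: GridRaster(np.full(shape, skipped), "skipped_pct", 10.0)},
                {0: GridRaster(np.full(shape, intensity_val), "intensity", 10.0),
                 1: GridRaster(np.full(shape, intensity_val), "intensity", 10.0)})

    def test_no_establishment_below_nhwl(self):
        cfg = SynthConfig(veg_intercept=10.0, seed=1)  # p would be ~1
        exps, ints = self._fields(0.0, 0.05)
        masks, true_p = evolve_vegetation(exps, ints, cfg)
        assert not masks[1].as_bool().any()
        assert np.all(true_p[(0, 1)].values == 0.0)

    def test_half_probability_realised_fraction(self):
        cfg = SynthConfig(veg_intercept=0.0, veg_coef_skipped=0.0,
                          veg_coef_intensity=0.0, seed=2)
        exps, ints = self._fields(50.0, 0.02)
        masks, _ = evolve_vegetation(exps, ints, cfg)
        frac = masks[1].as_bool().mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(frac - 0.5) <= 3 * se

    def test_certain_establishment(self):
        cfg = SynthConfig(veg_intercept=50.0, seed=3)
        exps, ints = self._fields(50.0, 0.02)
        masks, _ = evolve_vegetation(exps, ints, cfg)
        assert masks[1].as_bool().all()

    def test_persistence(self, small_scene):
        years = small_scene.config.years
        prev = small_scene.truth.veg_masks[years[0]].as_bool()
        for y in years[1:]:
            cur = small_scene.truth.veg_masks[y].as_bool()
            assert np.all(cur | ~prev)  # once vegetated, stays vegetated
            prev = cur

    def test_truth_probability_zero_where_skipped_zero(self, small_scene):
        years = small_scene.config.years
        for (y0, _y1), p in small_scene.truth.true_p.items():
            zero = small_scene.exposure_10m[y0].values == 0.0
            assert np.all(p.values[zero] == 0.0)


class TestSceneInvariants:
    def test_exposure_realism(self, small_scene):
        y = small_scene.config.years[-1]
        e = small_scene.exposure_10m[y].values
        assert (e == 0).any()
        assert (e > 50).any()

    def test_scene_determinism(self, small_config):
        a = generate_scene(small_config)
        b = generate_scene(small_config)
        y = small_config.years[-1]
        assert np.array_equal(a.dems[y].values, b.dems[y].values)
        assert np.array_equal(a.orthos[y].nir.values, b.orthos[y].nir.values)
        assert np.array_equal(a.truth.veg_masks[y].values, b.truth.veg_masks[y].values)
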