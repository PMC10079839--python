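"""Fully synthetic estuary with known ground truth.

Generates the inputs the analysis pipeline expects - multi-station
semidiurnal tides, an accreting convex tidal-flat DEM time series,
false-colour orthophotos, and stochastic vegetation dynamics - with the
statistical structure the analyses assume, so every downstream stage can be
tested offline against truth.

The scene is built on a regular 1-m grid.  Columns run along the estuary
axis (tidal amplitude grows linearly with the column coordinate); rows run
cross-shore, from a high, gently sloping anterior flat at the top, over a
convex shoulder, down to the channel.  Per year the flat accretes
uniformly.  Ridge-runnel texture (anisotropic sinusoid modulated by
spectral noise, relief of a few cm) is planted only where the pre-texture
slope is below the pattern slope ceiling and the bed sits above neap high
water; mega-ripples are added below the zero-exposure elevation, and a few
creeks are incised with walls well above the 3-degree creek cutoff.

NIR reflectance couples to micro-relief (runnels and pools are darker), so
the windowed SD of NIR rises where texture was planted.  Vegetation
establishes per 10-m tile as an independent Bernoulli draw with
p = logistic(b0 + a*skipped% + b*intensity), forced to zero below neap high
water, and persists once established.  The per-tile p fields are retained
as ground truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from ._rng import substream
from .errors import CoRegistrationError, InvalidConfigError
from .raster import GridRaster, block_resample, slope_deg
from .tides import ExposureCurve, WaterLevelSeries, exposure_curve, exposure_raster
from .vegetation import OrthoImage

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticScene",
    "gen_tide_series",
    "gen_dem_series",
    "gen_ortho",
    "evolve_vegetation",
    "generate_scene",
    "gen_calibration_scene",
]

M2_PERIOD_H = 12.42
S2_PERIOD_H = 12.00


@dataclass
class SynthConfig:
    """Parameters of the synthetic estuary.

    Heights are cm above datum, horizontal distances metres.  The defaults
    describe a macro-tidal estuary in transition: an upper flat spanning the
    neap-to-spring high water band, accreting 2 cm per year, with metre-
    scale ridge-runnel texture (relief well under the 10 cm envelope)
    confined to the gently sloping anterior section.
    """

    # grid
    grid_shape: tuple[int, int] = (520, 800)
    cell_size: float = 1.0
    years: tuple[int, ...] = tuple(range(2004, 2014))
    # accretion
    accretion_cm_yr: float = 2.0
    accretion_full_elev_cm: float = 0.0    # full accretion at/above this initial elevation
    accretion_zero_elev_cm: float = -100.0  # none at/below this
    # cross-shore profile (rows): gentle anterior flat, convex shoulder, channel
    flat_top_cm: float = 210.0
    anterior_grad_cm_per_m: float = 0.25
    shoulder_row: float = 380.0
    shoulder_width_m: float = 45.0
    shoulder_drop_cm: float = 400.0
    # ridge-runnel patterning
    pattern_wavelength_m: float = 3.0
    pattern_relief_cm: float = 8.0
    pattern_slope_ceiling_deg: float = 0.3
    pattern_min_elev_cm: float = 110.0     # ~ neap high water
    # creeks
    creek_count: int = 3
    creek_depth_cm: float = 40.0
    creek_width_m: float = 1.5
    # mega-ripples (lower intertidal)
    megaripple_wavelength_m: float = 18.0
    megaripple_relief_cm: float = 20.0
    # tides
    m2_amplitude_cm: float = 150.0
    s2_amplitude_cm: float = 40.0
    station_positions_m: tuple[float, ...] = (0.0, 400.0, 800.0)
    station_amplification: tuple[float, ...] = (1.0, 1.1, 1.2)
    tide_noise_sd_cm: float = 5.0
    tide_duration_days: float = 35.0
    tide_sampling_min: float = 10.0
    # vegetation logistic: p = sigmoid(b0 + a * skipped% + b * intensity)
    veg_intercept: float = -10.0
    veg_coef_skipped: float = 0.08
    veg_coef_intensity: float = 80.0
    # orthophoto rendering
    nir_base: float = 0.35
    nir_wetness_coef: float = 0.01         # NIR units per cm of micro-relief residual
    ortho_highpass_sigma_m: float = 3.0    # scale separating micro-relief from profile
    nir_saturation_cm: float = 4.0         # wetness darkening saturates beyond this relief
    pool_darkening: float = 0.05
    sensor_noise_sd: float = 0.005
    red_ratio: float = 0.82
    veg_nir_mean: float = 0.55
    veg_nir_sd: float = 0.03
    veg_red_mean: float = 0.12
    veg_red_sd: float = 0.02
    # analysis resolution
    tile_m: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_relief_cm > 10.0:
            raise InvalidConfigError(
                "ridge-runnel relief exceeds the 10 cm micro-topography envelope"
            )
        if self.accretion_cm_yr < 0:
            raise InvalidConfigError("accretion rate must be >= 0")
        if self.m2_amplitude_cm <= 0 or self.s2_amplitude_cm <= 0:
            raise InvalidConfigError("tidal amplitudes must be > 0")
        if len(self.years) >= 2 and not all(
                b > a for a, b in zip(self.years, self.years[1:])):
            raise InvalidConfigError("years must be strictly increasing")
        if self.tide_sampling_min <= 0:
            raise InvalidConfigError("sampling interval must be > 0")
        if len(self.station_positions_m) != len(self.station_amplification):
            raise InvalidConfigError("one amplification factor per station is required")

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


@dataclass
class GroundTruth:
    """Known truth of a synthetic scene, for recovery tests."""

    veg_masks: dict[int, GridRaster]                 # 10 m boolean, per year
    true_p: dict[tuple[int, int], GridRaster]        # per interval, 10 m
    pattern_masks: dict[int, GridRaster]             # 1 m boolean, per year
    creek_mask: GridRaster                           # 1 m boolean
    exposure_curves: list[ExposureCurve]             # per station
    flat_mask: GridRaster                            # 1 m boolean (full-accretion zone)

    @property
    def first_establishment_year(self) -> int | None:
        for year in sorted(self.veg_masks):
            if self.veg_masks[year].as_bool().any():
                return year
        return None


@dataclass
class SyntheticScene:
    """All per-year artifacts of one synthetic estuary."""

    config: SynthConfig
    tide_series: list[WaterLevelSeries]
    dems: dict[int, GridRaster]            # 1 m elevation
    dems_10m: dict[int, GridRaster]
    exposure_1m: dict[int, GridRaster]
    exposure_10m: dict[int, GridRaster]
    orthos: dict[int, OrthoImage]
    intensity_10m: dict[int, GridRaster]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# noise helper
# ---------------------------------------------------------------------------

def _spectral_noise(shape: tuple[int, int], rng: np.random.Generator,
                    beta: float = 3.0) -> np.ndarray:
    """Periodic autocorrelated field with power spectrum ~ k^-beta,
    rescaled to zero mean and unit SD."""
    ny, nx = shape
    spec = np.fft.fft2(rng.standard_normal((ny, nx)))
    k = np.hypot(np.fft.fftfreq(nx)[None, :], np.fft.fftfreq(ny)[:, None])
    k[0, 0] = 1.0
    spec *= k ** (-beta / 2.0)
    spec[0, 0] = 0.0
    f = np.real(np.fft.ifft2(spec))
    f -= f.mean()
    sd = f.std(ddof=1)
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# tides
# ---------------------------------------------------------------------------

def gen_tide_series(config: SynthConfig,
                    station_positions: list[float] | None = None,
                    ) -> list[WaterLevelSeries]:
    """Semidiurnal M2+S2 water levels at each station.

    The two constituents are in phase at t = 0 (spring tide) and beat with
    the ~14.77-day spring-neap period; each station's signal is scaled by
    its along-estuary amplification factor, with seeded Gaussian noise on
    top.
    """
    if config.tide_sampling_min <= 0:
        raise InvalidConfigError("sampling interval must be > 0")
    positions = (list(station_positions) if station_positions is not None
                 else list(config.station_positions_m))
    dt_h = config.tide_sampling_min / 60.0
    t = np.arange(0.0, config.tide_duration_days * 24.0, dt_h)
    m2 = config.m2_amplitude_cm * np.cos(2 * np.pi * t / M2_PERIOD_H)
    s2 = config.s2_amplitude_cm * np.cos(2 * np.pi * t / S2_PERIOD_H)
    out = []
    for i, (pos, amp) in enumerate(zip(positions, config.station_amplification)):
        rng = substream(config.seed, f"tides-{i}")
        noise = (rng.standard_normal(t.size) * config.tide_noise_sd_cm
                 if config.tide_noise_sd_cm > 0 else 0.0)
        out.append(WaterLevelSeries(
            station=f"S{i}", position=float(pos),
            times_h=t, levels_cm=amp * (m2 + s2) + noise,
        ))
    return out


# ---------------------------------------------------------------------------
# DEM series
# ---------------------------------------------------------------------------

def _base_profile(config: SynthConfig) -> np.ndarray:
    ny, nx = config.grid_shape
    y = np.arange(ny, dtype=np.float64)[:, None] * config.cell_size
    z = (config.flat_top_cm
         - config.anterior_grad_cm_per_m * y
         - config.shoulder_drop_cm / (1.0 + np.exp(
             -(y - config.shoulder_row * config.cell_size) / config.shoulder_width_m)))
    return np.broadcast_to(z, (ny, nx)).copy()


def _creek_incision(config: SynthConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Incised creek depths (cm, positive) and the creek cell mask."""
    ny, nx = config.grid_shape
    depth = np.zeros((ny, nx))
    if config.creek_count == 0 or config.creek_depth_cm <= 0:
        return depth, depth > 0
    x = np.arange(nx, dtype=np.float64)
    y = np.arange(ny, dtype=np.float64)
    start_row = int(0.25 * ny)
    for _ in range(config.creek_count):
        x0 = rng.uniform(0.1 * nx, 0.9 * nx)
        meander = rng.uniform(5.0, 15.0)
        period = rng.uniform(120.0, 220.0)
        phase = rng.uniform(0, 2 * np.pi)
        xc = x0 + meander * np.sin(2 * np.pi * y / period + phase)
        ramp = np.clip((y - start_row) / 12.0, 0.0, 1.0)
        # compact (super-Gaussian) cross-section: sharp banks, no wide tails
        u2 = (x[None, :] - xc[:, None]) ** 2 / config.creek_width_m ** 2
        depth += (config.creek_depth_cm * ramp[:, None] * np.exp(-0.5 * u2 * u2))
    return depth, depth > 1.0


def gen_dem_series(config: SynthConfig) -> tuple[dict[int, GridRaster], GroundTruth]:
    """Per-year elevation rasters plus the construction ground truth.

    The vegetation truth fields of the returned :class:`GroundTruth` are
    left empty; :func:`generate_scene` fills them after the orthophoto and
    vegetation stages have run.
    """
    rng = substream(config.seed, "dem")
    ny, nx = config.grid_shape
    base = _base_profile(config)
    creek_depth, creek_cells = _creek_incision(config, substream(config.seed, "creeks"))

    # accretion weight: 1 on the flat, tapering to 0 toward the channel
    w = np.clip((base - config.accretion_zero_elev_cm)
                / (config.accretion_full_elev_cm - config.accretion_zero_elev_cm),
                0.0, 1.0)
    flat_mask = base >= config.accretion_full_elev_cm

    # static texture ingredients (the bed pattern persists between years)
    amp_field = np.clip(0.6 + 0.6 * _spectral_noise((ny, nx), rng, beta=3.0), 0.0, 1.2)
    phase_field = 1.5 * _spectral_noise((ny, nx), rng, beta=3.0)
    xcoord = np.arange(nx, dtype=np.float64)[None, :] * config.cell_size
    carrier = np.sin(2 * np.pi * xcoord / config.pattern_wavelength_m + phase_field)
    ycoord = np.arange(ny, dtype=np.float64)[:, None] * config.cell_size
    ripple_carrier = np.sin(2 * np.pi * ycoord / config.megaripple_wavelength_m
                            + 0.8 * phase_field)

    dems: dict[int, GridRaster] = {}
    pattern_masks: dict[int, GridRaster] = {}
    year0 = config.years[0]
    for year in config.years:
        smooth = base + config.accretion_cm_yr * (year - year0) * w - creek_depth
        pre = GridRaster(smooth, "elevation", config.cell_size)
        pre_slope = slope_deg(pre).values

        plantable = ((pre_slope < config.pattern_slope_ceiling_deg)
                     & (smooth >= config.pattern_min_elev_cm))
        plantable &= np.isfinite(pre_slope)
        # texture intensifies as the flat climbs above neap high water and
        # fades toward the slope ceiling (patterns weaken near the boundary)
        growth = np.clip((smooth - config.pattern_min_elev_cm) / 20.0, 0.0, 1.0)
        ceiling = config.pattern_slope_ceiling_deg
        slope_fade = np.clip((ceiling - np.nan_to_num(pre_slope, nan=ceiling))
                             / (0.5 * ceiling), 0.0, 1.0) ** 2
        texture = np.where(
            plantable,
            0.5 * config.pattern_relief_cm * amp_field * growth * slope_fade * carrier,
            0.0,
        )

        ripple_zone = smooth < (config.pattern_min_elev_cm - 10.0)
        taper = np.clip(((config.pattern_min_elev_cm - 10.0) - smooth) / 30.0, 0.0, 1.0)
        ripples = np.where(ripple_zone,
                           0.5 * config.megaripple_relief_cm * taper * ripple_carrier,
                           0.0)

        dems[year] = GridRaster(smooth + texture + ripples, "elevation",
                                config.cell_size, meta={"year": int(year)})
        pattern_masks[year] = GridRaster(
            (plantable & (np.abs(texture) > 0)).astype(float), "boolean",
            config.cell_size, meta={"year": int(year)})

    truth = GroundTruth(
        veg_masks={}, true_p={}, pattern_masks=pattern_masks,
        creek_mask=GridRaster(creek_cells.astype(float), "boolean", config.cell_size),
        exposure_curves=[],
        flat_mask=GridRaster(flat_mask.astype(float), "boolean", config.cell_size),
    )
    return dems, truth


# ---------------------------------------------------------------------------
# orthophotos
# ---------------------------------------------------------------------------

def gen_ortho(dem: GridRaster, exposure: GridRaster, veg_mask: GridRaster,
              config: SynthConfig, rng: np.random.Generator | None = None,
              year: int | None = None) -> OrthoImage:
    """Render a false-colour orthophoto of one year.

    NIR = base level minus wetness darkening (micro-relief lows and
    permanently wet zero-exposure zones are darker) plus sensor noise;
    vegetated cells get a high-NIR / low-Red combination so their NDVI sits
    well above the sediment mode.  ``veg_mask`` may be at the analysis tile
    resolution; it is expanded to the image grid.
    """
    if dem.shape != exposure.shape:
        raise CoRegistrationError("DEM and exposure raster are not co-registered")
    if rng is None:
        rng = substream(config.seed, f"ortho-{year}")
    sigma_cells = config.ortho_highpass_sigma_m / dem.cell_size
    residual = dem.values - gaussian_filter(dem.values, sigma_cells, mode="nearest")

    # standing water below neap high water pools in the micro-lows;
    # darkening saturates once the surface is fully wet (or drained)
    pooled = (exposure.values <= 0) & (residual < 0)
    sat = np.clip(residual, -config.nir_saturation_cm, config.nir_saturation_cm)
    nir = (config.nir_base
           + config.nir_wetness_coef * sat
           - config.pool_darkening * pooled)
    red = config.red_ratio * nir

    if veg_mask.shape != dem.shape:
        f = int(round(veg_mask.cell_size / dem.cell_size))
        expanded = np.kron(veg_mask.as_bool(), np.ones((f, f), dtype=bool))
        veg = np.zeros(dem.shape, dtype=bool)
        ny, nx = min(expanded.shape[0], dem.shape[0]), min(expanded.shape[1], dem.shape[1])
        veg[:ny, :nx] = expanded[:ny, :nx]
    else:
        veg = veg_mask.as_bool()

    nveg = int(veg.sum())
    nir = np.where(veg, config.veg_nir_mean, nir)
    red = np.where(veg, config.veg_red_mean, red)
    if nveg:
        nir[veg] += rng.standard_normal(nveg) * config.veg_nir_sd
        red[veg] += rng.standard_normal(nveg) * config.veg_red_sd
    if config.sensor_noise_sd > 0:
        nir = nir + rng.standard_normal(dem.shape) * config.sensor_noise_sd
        red = red + rng.standard_normal(dem.shape) * config.sensor_noise_sd
    red = np.clip(red, 0.01, None)
    nir = np.clip(nir, 0.01, None)

    mk = {"year": year}
    return OrthoImage(
        nir=GridRaster(nir, "reflectance", dem.cell_size, dem.origin, dict(mk, band="nir")),
        red=GridRaster(red, "reflectance", dem.cell_size, dem.origin, dict(mk, band="red")),
        year=year,
    )


# ---------------------------------------------------------------------------
# vegetation dynamics
# ---------------------------------------------------------------------------

def _establishment_probability(exposure: np.ndarray, intensity: np.ndarray,
                               config: SynthConfig) -> np.ndarray:
    logit = (config.veg_intercept
             + config.veg_coef_skipped * exposure
             + config.veg_coef_intensity * intensity)
    p = 1.0 / (1.0 + np.exp(-logit))
    return np.where(exposure <= 0.0, 0.0, p)


def _step_establish(veg: np.ndarray, exposure: GridRaster, intensity: GridRaster,
                    config: SynthConfig, y0: int, y1: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One establishment interval: Bernoulli draws on not-yet-vegetated
    tiles; returns (new vegetation mask, true p field)."""
    rng = substream(config.seed, f"veg-{y0}-{y1}")
    p = _establishment_probability(exposure.values, intensity.values, config)
    p = np.where(np.isfinite(p), p, 0.0)
    draws = rng.random(veg.shape) < p
    return veg | (draws & ~veg), p


def evolve_vegetation(exposures: dict[int, GridRaster],
                      intensities: dict[int, GridRaster],
                      config: SynthConfig,
                      ) -> tuple[dict[int, GridRaster], dict[tuple[int, int], GridRaster]]:
    """Stochastic per-tile establishment over the scene's years.

    Establishment over the interval (y0, y1) is an independent Bernoulli
    draw per at-risk tile with p = logistic in the earlier year's skipped %
    and intensity, forced to zero below neap high water; established tiles
    persist.  Returns the per-year masks and the per-interval true p
    fields.
    """
    years = sorted(exposures)
    shape = exposures[years[0]].shape
    cell = exposures[years[0]].cell_size
    veg = np.zeros(shape, dtype=bool)
    masks: dict[int, GridRaster] = {
        years[0]: GridRaster(veg.astype(float), "boolean", cell,
                             meta={"year": int(years[0])})
    }
    true_p: dict[tuple[int, int], GridRaster] = {}
    for y0, y1 in zip(years[:-1], years[1:]):
        veg, p = _step_establish(veg, exposures[y0], intensities[y0], config, y0, y1)
        masks[y1] = GridRaster(veg.astype(float), "boolean", cell,
                               meta={"year": int(y1)})
        true_p[(y0, y1)] = GridRaster(p, "skipped_pct", cell,
                                      meta={"interval": (int(y0), int(y1)),
                                            "semantic": "probability"})
    return masks, true_p


# ---------------------------------------------------------------------------
# full scene
# ---------------------------------------------------------------------------

def generate_scene(config: SynthConfig) -> SyntheticScene:
    """Generate tides, DEMs, orthophotos, intensity and vegetation for all
    years, sequentially coupled: each interval's establishment draws use the
    earlier year's exposure and measured pattern intensity."""
    from .microtopo import intensity as intensity_op

    series = gen_tide_series(config)
    curves = [exposure_curve(s) for s in series]
    dems, truth = gen_dem_series(config)
    truth.exposure_curves = curves

    dems_10m, exp1, exp10, orthos, inten10 = {}, {}, {}, {}, {}
    veg = {config.years[0]: GridRaster(
        np.zeros((config.grid_shape[0] // int(config.tile_m),
                  config.grid_shape[1] // int(config.tile_m))),
        "boolean", config.tile_m, meta={"year": int(config.years[0])})}

    for year in config.years:
        dem = dems[year]
        dems_10m[year] = block_resample(dem, config.tile_m, "mean")
        exp1[year] = exposure_raster(dem, curves)
        exp10[year] = exposure_raster(dems_10m[year], curves)
        ortho = gen_ortho(dem, exp1[year], veg[year], config, year=year)
        orthos[year] = ortho
        inten10[year] = intensity_op(ortho, config.tile_m)
        if year != config.years[-1]:
            nxt = config.years[config.years.index(year) + 1]
            new_veg, p = _step_establish(veg[year].as_bool(), exp10[year],
                                         inten10[year], config, year, nxt)
            veg[nxt] = GridRaster(new_veg.astype(float), "boolean",
                                  config.tile_m, meta={"year": int(nxt)})
            truth.true_p[(year, nxt)] = GridRaster(
                p, "skipped_pct", config.tile_m,
                meta={"interval": (int(year), int(nxt)), "semantic": "probability"})

    truth.veg_masks = veg
    return SyntheticScene(config, series, dems, dems_10m, exp1, exp10,
                          orthos, inten10, truth)


# ---------------------------------------------------------------------------
# calibration scene (high-resolution DEM/NIR tile pairs)
# ---------------------------------------------------------------------------

def gen_calibration_scene(seed: int = 0, tiles: tuple[int, int] = (24, 32),
                          cell: float = 0.25, tile_m: float = 10.0,
                          coupled: bool = True,
                          config: SynthConfig | None = None,
                          ) -> tuple[GridRaster, OrthoImage]:
    """25-cm DEM and matching NIR image for metric calibration.

    Emulates the terrestrial-lidar calibration setup: ridge-runnel texture
    whose amplitude varies smoothly across the scene, and NIR reflectance
    coupled (or, for the null case, uncoupled) to the micro-relief, so that
    windowed SD of slope and windowed SD of NIR can be regressed per 10-m
    tile.
    """
    if config is None:
        config = SynthConfig(seed=seed)
    rng = substream(seed, "calibration")
    f = int(round(tile_m / cell))
    ny, nx = tiles[0] * f, tiles[1] * f

    log_amp = 1.2 * _spectral_noise((ny, nx), rng, beta=4.0)
    amp = 0.5 * config.pattern_relief_cm * np.exp(log_amp - 0.7)
    xcoord = np.arange(nx)[None, :] * cell
    phase = 1.0 * _spectral_noise((ny, nx), rng, beta=3.0)
    texture = amp * np.sin(2 * np.pi * xcoord / config.pattern_wavelength_m + phase)
    dem = GridRaster(150.0 + texture, "elevation", cell)

    if coupled:
        residual = texture
    else:
        amp2 = 0.5 * config.pattern_relief_cm * np.exp(
            1.2 * _spectral_noise((ny, nx), rng, beta=4.0) - 0.7)
        residual = amp2 * np.sin(2 * np.pi * xcoord / config.pattern_wavelength_m
                                 + 1.0 * _spectral_noise((ny, nx), rng, beta=3.0))
    nir = (config.nir_base + config.nir_wetness_coef * residual
           + rng.standard_normal((ny, nx)) * config.sensor_noise_sd)
    red = config.red_ratio * nir + rng.standard_normal((ny, nx)) * config.sensor_noise_sd
    ortho = OrthoImage(
        nir=GridRaster(nir, "reflectance", cell, meta={"band": "nir"}),
        red=GridRaster(np.clip(red, 0.01, None), "reflectance", cell,
                       meta={"band": "red"}),
    )
    return dem, ortho
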