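"""Orchestration: tie the stages into the three estuary-scale analyses.

The pipeline sequences tides -> exposure -> vegetation -> intensity ->
masks -> analyses over a manifest of per-year scenes, and writes CSV/JSON
artifacts plus a provenance log.  `run_demo` generates a fully synthetic
estuary and two indicator-scenario flats, runs everything end to end, and
reports recovered quantities next to the known truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import substream
from .errors import InvalidConfigError, UnimodalDistributionError
from .indicators import (
    IndicatorReport,
    annual_trend,
    early_indicator_report,
    establishment_array,
    hypsometric_curve,
    intensity_by_slope,
    YearPair,
)
from .microtopo import analysis_mask, calibrate_intensity, intensity as intensity_op
from .raster import GridRaster, apply_masks, block_resample, focal_sd, slope_deg
from .synth import (
    SynthConfig,
    SyntheticScene,
    gen_calibration_scene,
    generate_scene,
)
from .tides import (
    exposure_curve,
    exposure_raster,
    read_water_levels,
    write_water_levels,
)
from .vegetation import OrthoImage, classify_vegetation, fit_ndvi_threshold, ndvi, new_establishment

__all__ = [
    "RunConfig",
    "SceneEntry",
    "run_pipeline",
    "run_demo",
    "analyze_scene",
    "save_scene",
    "indicator_scenario_configs",
    "first_flag_year",
]


# ---------------------------------------------------------------------------
# file-based runs
# ---------------------------------------------------------------------------

@dataclass
class SceneEntry:
    year: int
    dem: str
    nir: str | None = None
    red: str | None = None
    veg_mask: str | None = None


@dataclass
class RunConfig:
    scenes: list[SceneEntry]
    stations_csv: str
    out_dir: str
    seed: int = 0
    axis: str = "x"
    tile_m: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        scenes = [SceneEntry(**s) for s in d.pop("scenes")]
        cfg = cls(scenes=scenes, **d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = []
        for s in self.scenes:
            for p in (s.dem, s.nir, s.red, s.veg_mask):
                if p is not None and not Path(p).exists():
                    missing.append(p)
        if not Path(self.stations_csv).exists():
            missing.append(self.stations_csv)
        if missing:
            raise InvalidConfigError(f"missing input path(s): {missing}")
        years = [s.year for s in self.scenes]
        if years != sorted(years):
            raise InvalidConfigError("scene years must be sorted")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis over a file manifest; returns the report
    dict and writes all artifacts under ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    series = read_water_levels(cfg.stations_csv)
    curves = [exposure_curve(s) for s in series]

    years, dem10s, exp10s, int10s, veg10s, slope2s = [], {}, {}, {}, {}, {}
    threshold_rows = []
    for entry in cfg.scenes:
        y = entry.year
        years.append(y)
        dem = GridRaster.load(entry.dem)
        dem10 = dem if dem.cell_size == cfg.tile_m else block_resample(dem, cfg.tile_m, "mean")
        dem10s[y] = dem10
        exp10s[y] = exposure_raster(dem10, curves, axis=cfg.axis)
        if dem.cell_size <= 2.0:
            dem2 = dem if dem.cell_size == 2.0 else block_resample(dem, 2.0, "mean")
            slope2s[y] = slope_deg(dem2)
        if entry.veg_mask is not None:
            veg = GridRaster.load(entry.veg_mask)
            veg.meta.setdefault("year", y)
            ortho = None
        else:
            nir = GridRaster.load(entry.nir)
            red = GridRaster.load(entry.red)
            ortho = OrthoImage(nir=nir, red=red, year=y)
            nd = ndvi(ortho)
            try:
                thr = fit_ndvi_threshold(nd.values[np.isfinite(nd.values)])
            except UnimodalDistributionError:
                # bare scene: a single (sediment) mode, nothing to classify
                thr = None
            threshold_rows.append({
                "year": y,
                "sediment_peak": thr.sediment_peak if thr else float("nan"),
                "veg_peak": thr.vegetation_peak if thr else float("nan"),
                "threshold": thr.threshold if thr else float("nan"),
            })
            if thr is None:
                veg = GridRaster(np.zeros(nd.shape), "boolean", nd.cell_size,
                                 nd.origin, {"year": y})
            else:
                veg = classify_vegetation(nd, thr)
            veg.meta.setdefault("year", y)
        veg10s[y] = veg if veg.cell_size == cfg.tile_m else block_resample(veg, cfg.tile_m, "max")
        if ortho is not None:
            int10s[y] = intensity_op(ortho, cfg.tile_m)

    report = analyze_scene(years, dem10s, exp10s, int10s, veg10s,
                           slope2_by_year=slope2s)
    if threshold_rows:
        pd.DataFrame(threshold_rows).to_csv(out / "ndvi_thresholds.csv", index=False)
    _write_analysis(report, out)
    provenance = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {s.dem: _sha256(s.dem) for s in cfg.scenes},
        "stations": _sha256(cfg.stations_csv),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return report


# ---------------------------------------------------------------------------
# in-memory analysis used by both file runs and the demo
# ---------------------------------------------------------------------------

def analyze_scene(years: list[int],
                  dem10s: dict[int, GridRaster],
                  exp10s: dict[int, GridRaster],
                  int10s: dict[int, GridRaster],
                  veg10s: dict[int, GridRaster],
                  slope2_by_year: dict[int, GridRaster] | None = None,
                  true_p: dict[tuple[int, int], GridRaster] | None = None,
                  ) -> dict:
    """Run the estuary-scale analyses on co-registered 10-m series."""
    report: dict = {"years": list(years)}

    # hypsometry and trends
    report["hypsometry"] = {y: hypsometric_curve(exp10s[y], year=y) for y in years}
    valid_all = np.logical_and.reduce([np.isfinite(dem10s[y].values) for y in years])
    not_veg_start = ~veg10s[years[0]].as_bool() if years[0] in veg10s else np.ones_like(valid_all)
    sel = valid_all & not_veg_start
    report["elevation_trend"] = annual_trend(
        [(y, float(dem10s[y].values[sel].mean())) for y in years])
    report["skipped_trend"] = annual_trend(
        [(y, float(exp10s[y].values[sel].mean())) for y in years])

    # establishment surface
    pairs = []
    for y0, y1 in zip(years[:-1], years[1:]):
        if y0 not in int10s or y0 not in veg10s or y1 not in veg10s:
            continue
        newv = new_establishment(veg10s[y0], veg10s[y1])
        at_risk = GridRaster(
            (~veg10s[y0].as_bool() & np.isfinite(dem10s[y0].values)).astype(float),
            "boolean", newv.cell_size)
        pairs.append(YearPair(
            new_veg=newv, at_risk=at_risk, exposure=exp10s[y0],
            intensity=int10s[y0],
            true_p=true_p.get((y0, y1)) if true_p else None))
    if pairs:
        report["establishment"] = establishment_array(pairs)

    # intensity vs slope on the masked latest scene with an intensity image
    int_years = [y for y in years if y in int10s]
    if int_years:
        y = int_years[-1]
        slope10 = slope_deg(dem10s[y])
        slope2 = (slope2_by_year or {}).get(y)
        if slope2 is None or slope2.cell_size >= 10.0:
            slope2 = slope10  # fall back: creek cutoff on the 10-m slope
            excl = GridRaster(
                ((veg10s[y].values > 0.5) | ~np.isfinite(exp10s[y].values)
                 | (exp10s[y].values <= 0) | (slope10.values > 3.0)).astype(float),
                "boolean", slope10.cell_size, exp10s[y].origin)
        else:
            excl = analysis_mask(veg10s[y], exp10s[y], slope2)
        masked_int = apply_masks(int10s[y], [excl])
        masked_slope = apply_masks(slope10, [excl])
        report["intensity_by_slope"] = intensity_by_slope(masked_int, masked_slope)
        report["exclusion_fraction"] = float(np.nanmean(excl.values))
    return report


def _write_analysis(report: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for y, curve in report.get("hypsometry", {}).items():
        curve.to_frame().to_csv(out / f"hypsometry_{y}.csv", index=False)
    if "establishment" in report:
        report["establishment"].to_frame().to_csv(out / "establishment_array.csv",
                                                  index=False)
    if "intensity_by_slope" in report:
        report["intensity_by_slope"].to_csv(out / "intensity_by_slope.csv", index=False)
    trends = {}
    for key in ("elevation_trend", "skipped_trend"):
        if key in report:
            t = report[key]
            trends[key] = {"slope": t.slope, "se": t.stderr, "n": t.n_years,
                           "ci": [t.ci_low, t.ci_high]}
    (out / "trends.json").write_text(json.dumps(trends, indent=1))


# ---------------------------------------------------------------------------
# scene export
# ---------------------------------------------------------------------------

def save_scene(scene: SyntheticScene, outdir: str | Path) -> None:
    """Write a synthetic scene to disk: DEM and band rasters per year, the
    water-level table, and a ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_water_levels(scene.tide_series, outdir / "water_levels.csv")
    for y in scene.config.years:
        scene.dems[y].save(outdir / f"dem_{y}.tif")
        scene.orthos[y].nir.save(outdir / f"nir_{y}.tif")
        scene.orthos[y].red.save(outdir / f"red_{y}.tif")
        scene.truth.veg_masks[y].save(outdir / f"veg_truth_{y}.tif")
    truth_summary = {
        "first_establishment_year": scene.truth.first_establishment_year,
        "years": list(scene.config.years),
        "seed": scene.config.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_summary, indent=1))
    scene.config.to_yaml(outdir / "synth_config.yaml")


# ---------------------------------------------------------------------------
# indicator scenario + demo
# ---------------------------------------------------------------------------

def indicator_scenario_configs(seed: int) -> tuple[SynthConfig, SynthConfig]:
    """Paired scenario flats for the early-indicator check.

    The first is an accreting, gently sloping flat whose crest starts just
    below neap high water and rises through it; establishment is possible
    but rare until the flat sits well above the boundary, so the indicator
    flag should precede the first establishment year.  The second is a
    static, steep (1 degree) control flat that must never be flagged.
    """
    common = dict(
        grid_shape=(200, 300),
        years=tuple(range(10)),
        shoulder_drop_cm=0.0,
        creek_count=0,
        megaripple_relief_cm=0.0,
        station_amplification=(1.0, 1.0, 1.0),
        station_positions_m=(0.0, 150.0, 300.0),
    )
    accreting = SynthConfig(
        accretion_cm_yr=3.0,
        flat_top_cm=106.0,
        anterior_grad_cm_per_m=0.18,   # ~0.10 degrees
        veg_intercept=-14.0,
        veg_coef_skipped=0.6,
        seed=seed,
        **common,
    )
    control = SynthConfig(
        accretion_cm_yr=0.0,
        flat_top_cm=150.0,
        anterior_grad_cm_per_m=1.75,   # ~1.0 degree
        veg_intercept=-30.0,           # effectively no establishment
        seed=seed + 1,
        **common,
    )
    return accreting, control


def first_flag_year(scene: SyntheticScene,
                    slope_threshold_deg: float = 0.3) -> tuple[int | None, IndicatorReport]:
    """Earliest year at which the unit is flagged 'approaching transition'.

    Evaluates the indicator on each growing prefix of the year series (at
    least 3 years of elevation data) and returns the first flagged year
    together with the final report.
    """
    years = list(scene.config.years)
    dem10 = [scene.dems_10m[y] for y in years]
    exp10 = [scene.exposure_10m[y] for y in years]
    slope10 = [slope_deg(d) for d in dem10]
    flag_year = None
    report = None
    for k in range(3, len(years) + 1):
        report = early_indicator_report(years[:k], dem10[:k], exp10[:k], slope10[:k],
                                        slope_threshold_deg)
        if report.flagged and flag_year is None:
            flag_year = years[k - 1]
    return flag_year, report


def run_demo(seed: int = 0, outdir: str | Path | None = None,
             sweep_nx: int = 64, sweep_reps: int = 3,
             config: SynthConfig | None = None) -> dict:
    """End-to-end demonstration on a seeded synthetic estuary.

    Generates the estuary, runs the full analysis, fits the calibration
    regressions, runs a scaled-down inclination sweep of the drainage
    model, evaluates the indicator scenario, and returns a report comparing
    recovered quantities with ground truth.
    """
    from .drainage import slope_sweep

    if config is None:
        config = SynthConfig(seed=seed)
    scene = generate_scene(config)
    years = list(config.years)
    report = analyze_scene(
        years, scene.dems_10m, scene.exposure_10m, scene.intensity_10m,
        scene.truth.veg_masks,
        slope2_by_year={y: slope_deg(block_resample(scene.dems[y], 2.0, "mean"))
                        for y in [years[-1]]},
        true_p=scene.truth.true_p)

    # calibration: coupled and decoupled high-resolution tile pairs
    def _fit(coupled: bool):
        dem, ortho = gen_calibration_scene(seed=seed + (0 if coupled else 7),
                                           coupled=coupled, config=config)
        sd_slope = focal_sd(slope_deg(dem), 10.0)
        inten = intensity_op(ortho, 10.0)
        return calibrate_intensity(sd_slope, inten)

    report["calibration_coupled"] = _fit(True)
    report["calibration_decoupled"] = _fit(False)

    # drainage: scaled-down inclination sweep
    report["sweep"] = slope_sweep([0.05, 0.5, 1.5], n_reps=sweep_reps,
                                  nx=sweep_nx, seed=seed)

    # indicator scenario
    acc_cfg, ctl_cfg = indicator_scenario_configs(seed)
    acc_scene = generate_scene(acc_cfg)
    ctl_scene = generate_scene(ctl_cfg)
    acc_flag, acc_report = first_flag_year(acc_scene)
    ctl_flag, ctl_report = first_flag_year(ctl_scene)
    report["indicator"] = {
        "accreting_flag_year": acc_flag,
        "accreting_first_establishment_year": acc_scene.truth.first_establishment_year,
        "accreting_report": acc_report.to_dict(),
        "control_flag_year": ctl_flag,
        "control_report": ctl_report.to_dict(),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_scene(scene, outdir / "scene")
        _write_analysis(report, outdir)
        report["sweep"].to_csv(outdir / "sweep.csv", index=False)
        (outdir / "demo_report.json").write_text(json.dumps({
            "indicator": report["indicator"],
            "calibration_coupled": report["calibration_coupled"].to_dict(),
            "calibration_decoupled": report["calibration_decoupled"].to_dict(),
            "seed": seed,
            "version": __version__,
        }, indent=1, default=float))
    return report
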