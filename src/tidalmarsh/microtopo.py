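"""Micro-topographic pattern intensity from NIR imagery.

Ridge-runnel micro-topography (metre-scale relief of a few cm) is often
invisible to airborne lidar but clearly modulates the near-infrared
reflectance of the sediment surface, because runnels stay wet or pooled
while ridges drain.  The *intensity* of micro-topography is therefore
measured as the sample standard deviation of the NIR band in 10 x 10 m
tiles.  The metric is shift-invariant in the band values but not
scale-invariant, so uncalibrated digital numbers are acceptable as long as
a scene is internally consistent.

Other features also produce high windowed NIR variance and must be
excluded before any pattern analysis: vegetated cells, mega-ripples in the
lower intertidal (removed by keeping only cells that skip > 0% of
inundations, i.e. above neap high water), and tidal creeks (cells whose
2-m slope exceeds 3 degrees, block-max resampled to 10 m so that
creek-adjacent cells drop out too).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import InsufficientDataError, InvalidArgumentError
from .raster import GridRaster, block_resample, focal_sd
from .vegetation import OrthoImage

__all__ = [
    "CalibrationFit",
    "intensity",
    "analysis_mask",
    "calibrate_intensity",
]


@dataclass
class CalibrationFit:
    """Log-log OLS fit of image intensity against slope variability."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    n_dropped_nonpositive: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("slope", "intercept", "r_squared", "f_statistic", "p_value",
                 "n", "n_dropped_nonpositive")}


def intensity(img: OrthoImage, window_m: float = 10.0,
              band: str = "nir") -> GridRaster:
    """Windowed SD of the NIR band in non-overlapping ``window_m`` tiles.

    ``band`` may name an alternate band ("red"/"green") as a greyscale
    fallback when NIR is unavailable; the choice is recorded in the output
    metadata.
    """
    try:
        src: GridRaster = getattr(img, band)
    except AttributeError:
        raise InvalidArgumentError(f"no such band {band!r}") from None
    if src is None:
        raise InvalidArgumentError(f"band {band!r} is not present in the image")
    out = focal_sd(src, window_m)
    out.kind = "intensity"
    out.meta.update({"band": band, "year": img.year, "window_m": window_m})
    return out


def analysis_mask(veg: GridRaster, exposure: GridRaster, slope_2m: GridRaster,
                  creek_slope_deg: float = 3.0, out_cell: float = 10.0) -> GridRaster:
    """Boolean exclusion mask at the analysis resolution (10 m).

    A tile is excluded when it is vegetated, at or below neap high water
    (skipped % = 0, the mega-ripple zone), or adjacent to a creek.  Creek
    cells are those steeper than ``creek_slope_deg`` at the fine (2 m)
    resolution; the block-max resample to the output grid plus a one-cell
    dilation drops the adjacent tiles too, whose coarse slope estimate is
    corrupted by the incision in their 3x3 stencil.  Nodata in the exposure
    raster also excludes the tile.
    """
    if slope_2m.cell_size >= out_cell:
        raise InvalidArgumentError(
            "creek detection requires slope at finer resolution than the output"
        )
    # creek component: fine-slope > cutoff, block-max to the output grid,
    # then one-cell dilation for the adjacent tiles
    creek_fine = slope_2m.with_values(
        np.where(np.isfinite(slope_2m.values),
                 (slope_2m.values > creek_slope_deg).astype(float), np.nan),
        kind="boolean")
    creek = block_resample(creek_fine, out_cell, "max")
    from scipy.ndimage import binary_dilation

    creek.values = binary_dilation(creek.values > 0.5,
                                   structure=np.ones((3, 3), bool)).astype(float)

    veg10 = veg if veg.cell_size == out_cell else block_resample(veg, out_cell, "max")
    exp10 = exposure if exposure.cell_size == out_cell else block_resample(exposure, out_cell, "mean")

    shapes = {creek.shape, veg10.shape, exp10.shape}
    if len(shapes) != 1:
        raise InvalidArgumentError(f"mask components disagree in shape: {shapes}")

    excluded = (
        (veg10.values > 0.5)
        | ~np.isfinite(exp10.values)
        | (exp10.values <= 0.0)
        | (creek.values > 0.5)
    )
    return GridRaster(excluded.astype(np.float64), "boolean", out_cell,
                      exposure.origin, {"creek_slope_deg": creek_slope_deg})


def calibrate_intensity(sd_slope_10m: GridRaster, intensity_10m: GridRaster) -> CalibrationFit:
    """OLS of log(intensity) on log(SD of slope) over paired valid tiles.

    Mirrors the field calibration of the image metric against slope
    variability from high-resolution elevation data.  Tiles where either
    variable is zero or negative are dropped (log domain) and counted.
    """
    x = sd_slope_10m.values.ravel()
    y = intensity_10m.values.ravel()
    finite = np.isfinite(x) & np.isfinite(y)
    positive = finite & (x > 0) & (y > 0)
    n_dropped = int(finite.sum() - positive.sum())
    if positive.sum() < 3:
        raise InsufficientDataError(
            f"need at least 3 positive pairs, got {int(positive.sum())}"
        )
    lx, ly = np.log(x[positive]), np.log(y[positive])
    model = sm.OLS(ly, sm.add_constant(lx)).fit()
    return CalibrationFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(model.nobs),
        n_dropped_nonpositive=n_dropped,
    )
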