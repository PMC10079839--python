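"""Frequency of skipped tidal inundations from water-level time series.

The central quantity is the percentage of high tides whose peak does not
reach above a given elevation::

    skipped(%) = (1 - cycles_inundated / cycles_total) * 100

Elevations at or below the neap high water level (NHWL, the lowest high tide
of the spring-neap cycle) skip 0% of inundations; elevations above the
highest spring tide skip 100%.  A tide *inundates* an elevation only when
its peak level is strictly greater than that elevation, so a peak exactly
equal to the elevation counts as skipped.

Multiple gauge stations along the estuary axis are combined by per-elevation
linear interpolation of the skipped percentage between the two bracketing
stations, clamped to the nearest station outside the covered range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidArgumentError, UndefinedMetricError
from .raster import GridRaster

__all__ = [
    "WaterLevelSeries",
    "ExposureCurve",
    "extract_high_tides",
    "skipped_fraction",
    "exposure_curve",
    "interpolate_exposure",
    "exposure_raster",
    "read_water_levels",
    "write_water_levels",
]


@dataclass
class WaterLevelSeries:
    """Tide-gauge record: station id, along-axis position (m), times (h)
    and levels (cm, common vertical datum)."""

    station: str
    position: float
    times_h: np.ndarray      # hours since epoch of the record, strictly increasing
    levels_cm: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=np.float64)
        self.levels_cm = np.asarray(self.levels_cm, dtype=np.float64)
        if self.times_h.ndim != 1 or self.times_h.shape != self.levels_cm.shape:
            raise InvalidArgumentError("times and levels must be matching 1-D arrays")
        if self.times_h.size >= 2 and not np.all(np.diff(self.times_h) > 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    @property
    def dt_h(self) -> float:
        return float(np.median(np.diff(self.times_h)))


@dataclass
class ExposureCurve:
    """Monotone step map from elevation (cm) to % skipped tidal inundations.

    ``elevations`` are the (sorted) step positions; ``skipped_pct[i]`` is the
    value attained for elevations in ``[elevations[i], elevations[i+1])``.
    Below the first step position the curve is ``base_pct`` (0 for a curve
    built from peaks).  Evaluation is exact for curves built from high-tide
    peaks: the step positions are exactly the peak levels.
    """

    elevations: np.ndarray
    skipped_pct: np.ndarray
    n_cycles_total: int
    position: float | None = None
    base_pct: float = 0.0

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=np.float64)
        self.skipped_pct = np.asarray(self.skipped_pct, dtype=np.float64)
        if np.any(np.diff(self.elevations) < 0):
            raise InvalidArgumentError("elevation grid must be sorted")
        if np.any(np.diff(self.skipped_pct) < -1e-12):
            raise InvalidArgumentError("skipped_pct must be non-decreasing in elevation")

    @classmethod
    def from_peaks(cls, peak_levels: np.ndarray, position: float | None = None
                   ) -> "ExposureCurve":
        levels = np.sort(np.asarray(peak_levels, dtype=np.float64))
        n = levels.size
        if n == 0:
            raise UndefinedMetricError("no high tides: skipped fraction is undefined")
        pct = 100.0 * np.arange(1, n + 1) / n  # = (1 - inundated/n) * 100
        # collapse duplicate levels, keeping the highest pct per level
        lev, idx = np.unique(levels[::-1], return_index=True)
        pct = pct[::-1][idx]
        return cls(lev, pct, n, position)

    def evaluate(self, elevation) -> np.ndarray:
        """Skipped % at the given elevation(s); right-continuous step."""
        e = np.asarray(elevation, dtype=np.float64)
        idx = np.searchsorted(self.elevations, e, side="right")
        vals = np.concatenate(([self.base_pct], self.skipped_pct))
        out = vals[idx]
        return np.where(np.isnan(e), np.nan, out)

    def __call__(self, elevation) -> np.ndarray:
        return self.evaluate(elevation)


def extract_high_tides(series: WaterLevelSeries, min_separation_h: float = 10.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """High-tide peaks of a level series.

    Local maxima (strictly above both neighbours) with an enforced minimum
    temporal separation; when two candidate peaks are closer than the
    separation, the higher one wins.  Returns ``(times_h, levels_cm)``; the
    number of peaks is ``cycles_total``.
    """
    if min_separation_h <= 0:
        raise InvalidArgumentError("min_separation must be > 0")
    if series.times_h.size < 3:
        warnings.warn("series too short to contain a high tide")
        return np.empty(0), np.empty(0)
    distance = max(1, int(np.ceil(min_separation_h / series.dt_h)))
    idx, _ = find_peaks(series.levels_cm, distance=distance)
    if idx.size == 0:
        warnings.warn(f"no high tides found in series {series.station!r}")
    return series.times_h[idx], series.levels_cm[idx]


def skipped_fraction(high_tide_levels: np.ndarray, elevation: float) -> float:
    """Percent of high tides whose peak does not exceed ``elevation``."""
    levels = np.asarray(high_tide_levels, dtype=np.float64)
    if levels.size == 0:
        raise UndefinedMetricError("no high tides: skipped fraction is undefined")
    skipped = levels.size - int(np.sum(levels > elevation))
    return 100.0 * skipped / levels.size


def exposure_curve(series: WaterLevelSeries,
                   elevation_grid: np.ndarray | None = None,
                   min_separation_h: float = 10.0) -> ExposureCurve:
    """Exposure curve of one station.

    Without an explicit grid the curve steps exactly at the peak levels and
    evaluation is exact at every elevation.  With a grid, the curve is
    tabulated at the grid elevations.
    """
    _, levels = extract_high_tides(series, min_separation_h)
    curve = ExposureCurve.from_peaks(levels, position=series.position)
    if elevation_grid is None:
        return curve
    grid = np.sort(np.asarray(elevation_grid, dtype=np.float64))
    return ExposureCurve(grid, curve.evaluate(grid), curve.n_cycles_total,
                         series.position, base_pct=float(curve.evaluate(grid[0])))


def interpolate_exposure(curves: list[ExposureCurve], query_position: float
                         ) -> ExposureCurve:
    """Per-elevation linear interpolation between the two bracketing stations.

    Outside the covered range the nearest station's curve is returned.  The
    result is tabulated on the union of the bracketing curves' step
    positions, which represents the mixed step function exactly.
    """
    if not curves:
        raise InvalidArgumentError("at least one exposure curve is required")
    for c in curves:
        if c.position is None:
            raise InvalidArgumentError("curves must carry station positions")
    curves = sorted(curves, key=lambda c: c.position)
    pos = np.array([c.position for c in curves])

    if query_position <= pos[0]:
        return curves[0]
    if query_position >= pos[-1]:
        return curves[-1]
    hi = int(np.searchsorted(pos, query_position, side="right"))
    lo = hi - 1
    if pos[hi] == pos[lo]:
        return curves[lo]
    w = (query_position - pos[lo]) / (pos[hi] - pos[lo])
    a, b = curves[lo], curves[hi]
    grid = np.union1d(a.elevations, b.elevations)
    mixed = (1.0 - w) * a.evaluate(grid) + w * b.evaluate(grid)
    base = (1.0 - w) * a.base_pct + w * b.base_pct
    n = round((1.0 - w) * a.n_cycles_total + w * b.n_cycles_total)
    return ExposureCurve(grid, mixed, n, query_position, base_pct=base)


def exposure_raster(dem: GridRaster, curves: list[ExposureCurve],
                    axis: str = "x") -> GridRaster:
    """Per-cell skipped % via the interpolated curve at each cell's axis
    coordinate.

    The estuary axis defaults to the raster x (column) coordinate; ``axis="y"``
    uses rows.  Nodata propagates.
    """
    if dem.kind != "elevation":
        raise InvalidArgumentError(f"exposure needs an elevation raster, got {dem.kind!r}")
    out = np.full(dem.shape, np.nan)
    if axis == "x":
        coords = dem.x_coords()
        for j, x in enumerate(coords):
            curve = interpolate_exposure(curves, float(x)) if len(curves) > 1 else curves[0]
            out[:, j] = curve.evaluate(dem.values[:, j])
    elif axis == "y":
        coords = dem.y_coords()
        for i, y in enumerate(coords):
            curve = interpolate_exposure(curves, float(y)) if len(curves) > 1 else curves[0]
            out[i, :] = curve.evaluate(dem.values[i, :])
    else:
        raise InvalidArgumentError("axis must be 'x' or 'y'")
    return GridRaster(out, "skipped_pct", dem.cell_size, dem.origin, dict(dem.meta))


# ---------------------------------------------------------------------------
# CSV I/O (station, position_m, timestamp_iso8601 or hours, level_cm)
# ---------------------------------------------------------------------------

def write_water_levels(series_list: list[WaterLevelSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "station": s.station,
            "position_m": s.position,
            "time_h": s.times_h,
            "level_cm": s.levels_cm,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_water_levels(path: str | Path) -> list[WaterLevelSeries]:
    df = pd.read_csv(path)
    out = []
    for station, g in df.groupby("station", sort=False):
        out.append(WaterLevelSeries(
            station=str(station),
            position=float(g["position_m"].iloc[0]),
            times_h=g["time_h"].to_numpy(),
            levels_cm=g["level_cm"].to_numpy(),
        ))
    return out
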