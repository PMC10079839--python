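"""Grid machinery shared by all imagery/DEM stages.

A :class:`GridRaster` is a rectangular 2-D field with a declared semantic
kind (elevation in cm, band reflectance, % skipped inundations, slope in
degrees, or boolean mask), a cell size in metres, a georeference origin and
a nodata contract.  Internally every raster is float64 with NaN as nodata;
boolean rasters store 0.0/1.0 and expose :meth:`GridRaster.as_bool`.

Files are written as single-band TIFF grids with a JSON sidecar carrying the
georeference and semantic metadata (``<path>.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import (
    CoRegistrationError,
    InvalidArgumentError,
    SemanticTypeError,
)

__all__ = [
    "GridRaster",
    "KINDS",
    "slope_deg",
    "block_resample",
    "focal_sd",
    "apply_masks",
]

KINDS = ("elevation", "reflectance", "skipped_pct", "slope", "boolean", "intensity")


@dataclass
class GridRaster:
    """A georeferenced 2-D field with a semantic kind.

    Parameters
    ----------
    values
        2-D float64 array; NaN marks nodata.  Boolean rasters use 0.0/1.0.
    kind
        One of :data:`KINDS`.
    cell_size
        Cell edge length in metres (> 0).
    origin
        ``(x, y)`` map coordinate of the top-left corner of the grid.
    meta
        Free-form provenance (source year, band, ...).
    """

    values: np.ndarray
    kind: str
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidArgumentError("raster values must be 2-D")
        if self.kind not in KINDS:
            raise SemanticTypeError(f"unknown raster kind {self.kind!r}")
        if not self.cell_size > 0:
            raise InvalidArgumentError("cell size must be > 0")

    # -- basic queries ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def as_bool(self) -> np.ndarray:
        """Boolean view of a boolean-kind raster; nodata maps to False."""
        if self.kind != "boolean":
            raise SemanticTypeError(f"raster kind is {self.kind!r}, not boolean")
        return np.nan_to_num(self.values, nan=0.0) > 0.5

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    **meta) -> "GridRaster":
        return GridRaster(values, kind or self.kind, self.cell_size,
                          self.origin, {**self.meta, **meta})

    def copy(self) -> "GridRaster":
        return self.with_values(self.values.copy())

    # -- cell coordinates -------------------------------------------------
    def x_coords(self) -> np.ndarray:
        """Map x coordinate of each column's cell centre."""
        x0 = self.origin[0]
        return x0 + (np.arange(self.shape[1]) + 0.5) * self.cell_size

    def y_coords(self) -> np.ndarray:
        y0 = self.origin[1]
        return y0 + (np.arange(self.shape[0]) + 0.5) * self.cell_size

    # -- I/O ---------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.values)
        sidecar = {
            "kind": self.kind,
            "cell_size": self.cell_size,
            "origin": list(self.origin),
            "nodata": "nan",
            "meta": self.meta,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GridRaster":
        import tifffile

        path = Path(path)
        values = np.asarray(tifffile.imread(path), dtype=np.float64)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        return cls(values, sidecar["kind"], sidecar["cell_size"],
                   tuple(sidecar["origin"]), sidecar.get("meta", {}))


def _check_coregistered(a: GridRaster, b: GridRaster) -> None:
    if a.shape != b.shape or a.cell_size != b.cell_size:
        raise CoRegistrationError(
            f"grids are not co-registered: {a.shape}@{a.cell_size} m vs "
            f"{b.shape}@{b.cell_size} m"
        )


# ---------------------------------------------------------------------------
# slope
# ---------------------------------------------------------------------------

def slope_deg(dem: GridRaster) -> GridRaster:
    """Horn 3x3 slope of an elevation raster, in degrees.

    Elevation is stored in cm and cell size in metres; the gradient is
    formed in consistent units (m per m) before taking the arctangent.
    Border cells, and cells whose 3x3 neighbourhood contains nodata, are
    nodata in the output.
    """
    if dem.kind != "elevation":
        raise SemanticTypeError(f"slope requires an elevation raster, got {dem.kind!r}")
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise InvalidArgumentError("slope requires at least a 3x3 grid")

    z = dem.values / 100.0  # cm -> m
    dx = dem.cell_size

    # 3x3 neighbourhood views of the interior
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * dx)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    out = np.full(dem.shape, np.nan)
    out[1:-1, 1:-1] = slope
    return GridRaster(out, "slope", dem.cell_size, dem.origin, dict(dem.meta))


# ---------------------------------------------------------------------------
# block aggregation
# ---------------------------------------------------------------------------

Aggregator = Literal["mean", "max", "sd"]


def _block_view(values: np.ndarray, f: int) -> np.ndarray:
    ny, nx = values.shape
    ny2, nx2 = (ny // f) * f, (nx // f) * f
    v = values[:ny2, :nx2]
    return v.reshape(ny2 // f, f, nx2 // f, f).swapaxes(1, 2).reshape(ny2 // f, nx2 // f, f * f)


def block_resample(r: GridRaster, target_cell: float, aggregator: Aggregator) -> GridRaster:
    """Aggregate non-overlapping blocks to a coarser, integer-multiple cell.

    ``mean`` uses all valid cells in the block; ``max`` and ``sd`` (sample
    standard deviation, n-1) require at least 2 valid cells, else nodata.
    Trailing rows/columns that do not fill a whole block are dropped.
    """
    ratio = target_cell / r.cell_size
    f = int(round(ratio))
    if f < 1 or abs(ratio - f) > 1e-9:
        raise InvalidArgumentError(
            f"target cell {target_cell} m is not an integer multiple of {r.cell_size} m"
        )
    if aggregator not in ("mean", "max", "sd"):
        raise InvalidArgumentError(f"unknown aggregator {aggregator!r}")
    if f == 1:
        return r.copy()

    blocks = _block_view(r.values, f)
    nvalid = np.isfinite(blocks).sum(axis=-1)
    with np.errstate(invalid="ignore"):
        if aggregator == "mean":
            out = np.where(nvalid >= 1, np.nanmean(np.where(np.isfinite(blocks), blocks, np.nan), axis=-1), np.nan)
        elif aggregator == "max":
            out = np.where(nvalid >= 2, np.nanmax(np.where(np.isfinite(blocks), blocks, -np.inf), axis=-1), np.nan)
        else:  # sd
            out = np.where(nvalid >= 2, _nansd(blocks), np.nan)
    kind = r.kind
    return GridRaster(out, kind, target_cell, r.origin, dict(r.meta))


def _nansd(blocks: np.ndarray) -> np.ndarray:
    """Sample SD (ddof=1) over the last axis, ignoring NaN.

    Two-pass (mean-subtracted) so constant blocks give exactly zero.
    """
    m = np.isfinite(blocks)
    n = m.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        # anchor on a member value so constant blocks give exactly zero
        anchor = np.nanmax(np.where(m, blocks, -np.inf), axis=-1)
        anchored = np.where(m, blocks - anchor[..., None], 0.0)
        mean = anchored.sum(axis=-1) / n
        dev = np.where(m, anchored - mean[..., None], 0.0)
        var = (dev * dev).sum(axis=-1) / (n - 1)
    return np.sqrt(np.maximum(var, 0.0))


def focal_sd(r: GridRaster, window: float, moving: bool = False) -> GridRaster:
    """Sample standard deviation of valid cells per window.

    The default (and the mode used throughout the analyses) tiles the grid
    into non-overlapping windows, producing an output at the window
    resolution.  ``moving=True`` computes the same statistic in a sliding
    window at native resolution instead; that mode is provided for
    exploration only.
    """
    if window < r.cell_size:
        raise InvalidArgumentError("window must be at least one cell")
    if not moving:
        return block_resample(r, window, "sd")

    f = int(round(window / r.cell_size))
    if abs(window / r.cell_size - f) > 1e-9:
        raise InvalidArgumentError("window must be an integer multiple of the cell size")
    from numpy.lib.stride_tricks import sliding_window_view

    pad = f // 2
    padded = np.pad(r.values, pad, constant_values=np.nan)
    win = sliding_window_view(padded, (f, f))[: r.shape[0], : r.shape[1]]
    win = win.reshape(win.shape[0], win.shape[1], f * f)
    n = np.isfinite(win).sum(axis=-1)
    out = np.where(n >= 2, _nansd(win), np.nan)
    return GridRaster(out, r.kind, r.cell_size, r.origin, dict(r.meta))


def apply_masks(r: GridRaster, masks: Iterable[GridRaster]) -> GridRaster:
    """Set cells flagged by any boolean mask to nodata (order-independent)."""
    out = r.values.copy()
    for m in masks:
        _check_coregistered(r, m)
        out[m.as_bool()] = np.nan
    return r.with_values(out)
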