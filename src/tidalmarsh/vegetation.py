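"""Vegetation classification from false-colour orthophotos.

Vegetation is mapped by thresholding NDVI = (NIR - Red) / (NIR + Red).
Because atmospheric conditions and seasonal timing shift the absolute NDVI
values between acquisition campaigns, the threshold is refit per scene: a
kernel density estimate of the NDVI sample is expected to be bimodal, with
a low sediment mode and a high vegetation mode, and the threshold is placed
half-way between the two most prominent modes.  Newly established vegetation
between two campaigns is the set of cells vegetated in the later year but
not in the earlier one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import (
    CoRegistrationError,
    InvalidArgumentError,
    UnimodalDistributionError,
)
from .raster import GridRaster

__all__ = [
    "OrthoImage",
    "NdviThreshold",
    "ndvi",
    "fit_ndvi_threshold",
    "classify_vegetation",
    "new_establishment",
]


@dataclass
class OrthoImage:
    """Co-registered NIR/Red (optionally Green) reflectance bands."""

    nir: GridRaster
    red: GridRaster
    green: GridRaster | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        bands = [self.red] + ([self.green] if self.green is not None else [])
        for b in bands:
            if b.shape != self.nir.shape or b.cell_size != self.nir.cell_size:
                raise CoRegistrationError("ortho bands are not co-registered")

    @property
    def cell_size(self) -> float:
        return self.nir.cell_size


@dataclass
class NdviThreshold:
    """Per-scene NDVI threshold: midpoint between sediment and vegetation
    density modes, with fit diagnostics."""

    sediment_peak: float
    vegetation_peak: float
    threshold: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.sediment_peak < self.threshold < self.vegetation_peak):
            raise InvalidArgumentError(
                "threshold must lie between the sediment and vegetation peaks"
            )


def ndvi(img: OrthoImage) -> GridRaster:
    """Per-cell NDVI; cells with NIR + Red = 0 are nodata."""
    n, r = img.nir.values, img.red.values
    denom = n + r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (n - r) / denom, np.nan)
    return GridRaster(out, "reflectance", img.nir.cell_size, img.nir.origin,
                      {"index": "ndvi", "year": img.year})


def fit_ndvi_threshold(ndvi_values: np.ndarray,
                       prominence_frac: float = 0.05,
                       grid_points: int = 512,
                       max_sample: int = 50_000,
                       rng: np.random.Generator | None = None) -> NdviThreshold:
    """Fit the per-scene bimodal threshold by peak analysis of a KDE.

    A Gaussian KDE with Silverman bandwidth is evaluated on a regular grid;
    modes are density maxima with prominence at least ``prominence_frac`` of
    the maximum density.  The two most prominent modes are taken as sediment
    (lower) and vegetation (upper), and the threshold is their arithmetic
    midpoint.  Samples larger than ``max_sample`` are subsampled for the KDE
    (deterministically unless an rng is given).

    Raises
    ------
    UnimodalDistributionError
        If fewer than two modes are detected; the caller may then supply a
        manual threshold.
    """
    x = np.asarray(ndvi_values, dtype=np.float64).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise InvalidArgumentError("too few NDVI values to fit a threshold")
    if x.size > max_sample:
        if rng is None:
            rng = np.random.default_rng(0)
        x = rng.choice(x, size=max_sample, replace=False)

    kde = gaussian_kde(x, bw_method="silverman")
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    density = kde(grid)

    peaks, props = find_peaks(density, prominence=prominence_frac * density.max())
    if peaks.size < 2:
        raise UnimodalDistributionError(
            f"found {peaks.size} density mode(s); a bimodal NDVI distribution is "
            "required (supply a manual threshold to proceed)"
        )
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    sed, veg = sorted(grid[top2])
    return NdviThreshold(
        sediment_peak=float(sed),
        vegetation_peak=float(veg),
        threshold=float((sed + veg) / 2.0),
        diagnostics={
            "bandwidth": float(kde.factor * x.std(ddof=1)),
            "n": int(x.size),
            "n_modes": int(peaks.size),
            "prominences": [float(p) for p in np.sort(props["prominences"])[::-1][:4]],
        },
    )


def classify_vegetation(ndvi_raster: GridRaster, thr: NdviThreshold | float) -> GridRaster:
    """Boolean vegetation mask: NDVI strictly greater than the threshold.

    A cell whose NDVI equals the threshold exactly is not vegetated; nodata
    propagates.
    """
    t = thr.threshold if isinstance(thr, NdviThreshold) else float(thr)
    if not (-1.0 < t < 1.0):
        raise InvalidArgumentError("NDVI threshold must lie in (-1, 1)")
    v = ndvi_raster.values
    out = np.where(np.isfinite(v), (v > t).astype(np.float64), np.nan)
    return GridRaster(out, "boolean", ndvi_raster.cell_size, ndvi_raster.origin,
                      {**ndvi_raster.meta, "threshold": t})


def new_establishment(mask_early: GridRaster, mask_late: GridRaster) -> GridRaster:
    """Cells vegetated in the later year but not in the earlier.

    Nodata in either year propagates; the two masks must be co-registered
    and must not refer to the same year.
    """
    if mask_early.shape != mask_late.shape or mask_early.cell_size != mask_late.cell_size:
        raise CoRegistrationError("vegetation masks are not co-registered")
    ye, yl = mask_early.meta.get("year"), mask_late.meta.get("year")
    if ye is not None and yl is not None:
        if ye == yl:
            raise InvalidArgumentError("early and late masks are from the same year")
        if ye > yl:
            raise InvalidArgumentError("early mask must precede late mask")
    e, l = mask_early.values, mask_late.values
    new = (l > 0.5) & ~(e > 0.5)
    out = np.where(np.isfinite(e) & np.isfinite(l), new.astype(np.float64), np.nan)
    return GridRaster(out, "boolean", mask_early.cell_size, mask_early.origin,
                      {"early_year": ye, "late_year": yl})
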