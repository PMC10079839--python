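"""Estuary-scale statistics and the composite early-indicator report.

This module houses the analyses run on the 10-m rasters produced upstream:

* hypsometric curves of the skipped-inundation percentage (relative area
  equalling or exceeding each value), per year;
* slope hypsometry by tidal-position bin (the "flatter the higher" check);
* linear trends of annual means (accretion rates, rising exposure);
* the mean micro-topographic intensity in 120 logarithmic slope bins;
* the 2-D establishment-probability surface: 101 bins of skipped % by 85
  bins of intensity, probability = newly vegetated / at-risk cells per bin,
  with bins under 30 observations suppressed;
* the early-indicator flag: an accreting flat above neap high water whose
  slope is below (or declining toward) the ~0.3 degree boundary at which
  micro-topographic patterning appears is labelled "approaching transition".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidArgumentError
from .raster import GridRaster

__all__ = [
    "HypsometricCurve",
    "TrendFit",
    "EstablishmentArray",
    "YearPair",
    "hypsometric_curve",
    "slope_hypsometry",
    "annual_trend",
    "intensity_by_slope",
    "establishment_array",
    "early_indicator_report",
    "DEFAULT_SLOPE_BOUNDARY_DEG",
]

DEFAULT_SLOPE_BOUNDARY_DEG = 0.3  # low-slope boundary for pattern formation


# ---------------------------------------------------------------------------
# hypsometry
# ---------------------------------------------------------------------------

@dataclass
class HypsometricCurve:
    """Relative area (%) of cells equalling or exceeding each value."""

    values: np.ndarray      # sorted ascending
    rel_area_pct: np.ndarray
    year: int | None = None
    n_cells: int = 0

    def evaluate(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=np.float64)
        # fraction of sample >= v; sorted ascending -> count = n - searchsorted(left)
        idx = np.searchsorted(self.values, v, side="left")
        return 100.0 * (self.values.size - idx) / self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "rel_area_pct": self.rel_area_pct,
                             "year": self.year})


def hypsometric_curve(exposure: GridRaster, year: int | None = None) -> HypsometricCurve:
    """Hypsometric curve of skipped % over the cells above neap high water.

    Only cells with skipped % > 0 enter the curve; the relative area at a
    value v is the percentage of those cells with skipped % >= v.
    """
    vals = exposure.values[np.isfinite(exposure.values)]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise InsufficientDataError("no valid cells above neap high water")
    s = np.sort(vals)
    rel = 100.0 * (s.size - np.arange(s.size)) / s.size  # area >= each sorted value
    return HypsometricCurve(s, rel, year=year, n_cells=s.size)


def slope_hypsometry(slope: GridRaster, exposure: GridRaster,
                     position_bins: np.ndarray) -> dict[tuple[float, float], HypsometricCurve]:
    """Slope hypsometric curves per skipped % bin.

    Cells are grouped by their tidal position (skipped %) into
    ``position_bins`` (edges covering (0, 100]); a hypsometric curve of
    slope is built per non-empty group.  Empty bins are absent from the
    result.
    """
    if slope.shape != exposure.shape:
        raise InvalidArgumentError("slope and exposure rasters must be co-registered")
    edges = np.asarray(position_bins, dtype=np.float64)
    out: dict[tuple[float, float], HypsometricCurve] = {}
    sv, ev = slope.values.ravel(), exposure.values.ravel()
    ok = np.isfinite(sv) & np.isfinite(ev) & (ev > 0)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = ok & (ev > lo) & (ev <= hi)
        vals = np.sort(sv[sel])
        if vals.size == 0:
            continue
        rel = 100.0 * (vals.size - np.arange(vals.size)) / vals.size
        out[(float(lo), float(hi))] = HypsometricCurve(vals, rel, n_cells=vals.size)
    return out


# ---------------------------------------------------------------------------
# trends
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """OLS trend of an annual mean: slope per year with SE and 95% CI."""

    slope: float
    stderr: float
    intercept: float
    n_years: int
    ci_low: float
    ci_high: float

    @property
    def excludes_zero(self) -> bool:
        return bool(np.isfinite(self.ci_low) and (self.ci_low > 0 or self.ci_high < 0))


def annual_trend(year_values: list[tuple[float, float]]) -> TrendFit:
    """Ordinary least squares of an annual mean value on year."""
    if len(year_values) < 2 or len({y for y, _ in year_values}) < 2:
        raise InvalidArgumentError("at least 2 distinct years are required")
    years = np.array([y for y, _ in year_values], dtype=np.float64)
    vals = np.array([v for _, v in year_values], dtype=np.float64)
    model = sm.OLS(vals, sm.add_constant(years)).fit()
    slope = float(model.params[1])
    if len(year_values) >= 3:
        se = float(model.bse[1])
        tcrit = sps.t.ppf(0.975, df=len(year_values) - 2)
        ci = (slope - tcrit * se, slope + tcrit * se)
    else:
        se, ci = float("nan"), (float("nan"), float("nan"))
    return TrendFit(slope, se, float(model.params[0]), len(year_values), ci[0], ci[1])


# ---------------------------------------------------------------------------
# intensity vs slope
# ---------------------------------------------------------------------------

def intensity_by_slope(intensity: GridRaster, slope: GridRaster,
                       n_bins: int = 120,
                       bounds_deg: tuple[float, float] = (0.01, 10.0)) -> pd.DataFrame:
    """Mean micro-topographic intensity in logarithmically spaced slope bins.

    Inputs are expected to have the exclusion mask already applied.  Returns
    a frame with one row per non-empty bin (bin_low, bin_high, center_deg,
    mean_intensity, se, n); empty bins are absent rather than zero.
    """
    if intensity.shape != slope.shape:
        raise InvalidArgumentError("intensity and slope must be co-registered")
    iv, sv = intensity.values.ravel(), slope.values.ravel()
    ok = np.isfinite(iv) & np.isfinite(sv) & (sv >= bounds_deg[0]) & (sv <= bounds_deg[1])
    if not ok.any():
        raise InsufficientDataError("no unmasked cells within the slope bounds")
    edges = np.logspace(np.log10(bounds_deg[0]), np.log10(bounds_deg[1]), n_bins + 1)
    idx = np.clip(np.digitize(sv[ok], edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        vals = iv[ok][sel]
        rows.append({
            "bin_low_deg": edges[b],
            "bin_high_deg": edges[b + 1],
            "center_deg": float(np.sqrt(edges[b] * edges[b + 1])),
            "mean_intensity": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            "n": n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# establishment surface
# ---------------------------------------------------------------------------

def skipped_bin_edges() -> np.ndarray:
    """Edges of the 101 skipped % bins.

    The first bin is the degenerate class {exactly 0} - the below-NHWL zone
    where establishment cannot occur - followed by 100 unit-width bins
    covering (0, 100].
    """
    return np.concatenate(([-0.5, 0.0], np.arange(1.0, 101.0)))
    # bin 0: [-0.5, 0]; with values in [0,100] this is exactly {0}


@dataclass
class YearPair:
    """One campaign interval contributing to the establishment surface.

    ``new_veg`` marks cells newly vegetated over the interval; ``at_risk``
    marks cells eligible for establishment (valid in both years and not
    vegetated in the earlier year).  ``exposure`` and ``intensity`` are the
    earlier-year explanatory rasters.  ``true_p`` optionally carries a known
    per-cell establishment probability (synthetic ground truth).
    """

    new_veg: GridRaster
    at_risk: GridRaster
    exposure: GridRaster
    intensity: GridRaster
    true_p: GridRaster | None = None


@dataclass
class EstablishmentArray:
    """2-D binned establishment probabilities (skipped % x intensity).

    ``n`` and ``k`` hold at-risk and newly-vegetated counts per bin;
    ``probability`` is k/n where n >= ``min_n`` and NaN (missing) elsewhere.
    ``p_true`` (when ground truth was supplied) is the per-bin mean of the
    true per-cell probability over the at-risk cells.
    """

    skipped_edges: np.ndarray
    intensity_edges: np.ndarray
    n: np.ndarray
    k: np.ndarray
    min_n: int = 30
    p_true_sum: np.ndarray | None = None
    n_pairs: int = 0
    prob_sum: np.ndarray | None = None   # for the unweighted per-pair mean mode
    pair_count: np.ndarray | None = None

    @property
    def probability(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.n >= self.min_n, self.k / np.maximum(self.n, 1), np.nan)
        return p

    @property
    def probability_pair_mean(self) -> np.ndarray:
        """Unweighted mean of per-pair proportions (fidelity mode)."""
        if self.prob_sum is None:
            raise InvalidArgumentError("array was built without per-pair proportions")
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.n >= self.min_n,
                         self.prob_sum / np.maximum(self.pair_count, 1), np.nan)
        return p

    @property
    def p_true(self) -> np.ndarray | None:
        if self.p_true_sum is None:
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n >= self.min_n,
                            self.p_true_sum / np.maximum(self.n, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export; bins with n < min_n are absent."""
        rows = []
        p = self.probability
        pt = self.p_true
        for i in range(self.n.shape[0]):
            for j in range(self.n.shape[1]):
                if self.n[i, j] >= self.min_n:
                    row = {
                        "skipped_low": self.skipped_edges[i],
                        "skipped_high": self.skipped_edges[i + 1],
                        "intensity_low": self.intensity_edges[j],
                        "intensity_high": self.intensity_edges[j + 1],
                        "n": int(self.n[i, j]),
                        "k": int(self.k[i, j]),
                        "p": p[i, j],
                    }
                    if pt is not None:
                        row["p_true"] = pt[i, j]
                    rows.append(row)
        return pd.DataFrame(rows)


def establishment_array(pairs: list[YearPair],
                        skipped_edges: np.ndarray | None = None,
                        intensity_edges: np.ndarray | None = None,
                        n_intensity_bins: int = 85,
                        min_n: int = 30) -> EstablishmentArray:
    """Pool campaign intervals into the 101 x 85 establishment surface.

    Counts (at-risk n, newly vegetated k) are summed across intervals and
    the probability is Sk/Sn per bin; the per-pair proportions are also
    accumulated so the unweighted-mean aggregation remains available.
    Intensity edges default to 85 linear bins between 0 and the pooled
    99.5th percentile of intensity over at-risk cells.
    """
    if not pairs:
        raise InvalidArgumentError("at least one year pair is required")
    if skipped_edges is None:
        skipped_edges = skipped_bin_edges()
    skipped_edges = np.asarray(skipped_edges, dtype=np.float64)

    def _pair_arrays(p: YearPair):
        risk = p.at_risk.as_bool() & np.isfinite(p.new_veg.values) \
            & np.isfinite(p.exposure.values) & np.isfinite(p.intensity.values)
        return (p.exposure.values[risk], p.intensity.values[risk],
                p.new_veg.values[risk] > 0.5,
                p.true_p.values[risk] if p.true_p is not None else None)

    prepared = [_pair_arrays(p) for p in pairs]
    if intensity_edges is None:
        pooled = np.concatenate([it for _, it, _, _ in prepared]) if prepared else np.empty(0)
        if pooled.size == 0:
            raise InsufficientDataError("no at-risk cells in any pair")
        hi = float(np.percentile(pooled, 99.5))
        if hi <= 0:
            hi = float(pooled.max()) or 1.0
        intensity_edges = np.linspace(0.0, hi, n_intensity_bins + 1)
    intensity_edges = np.asarray(intensity_edges, dtype=np.float64)

    nsb, nib = skipped_edges.size - 1, intensity_edges.size - 1
    n = np.zeros((nsb, nib), dtype=np.int64)
    k = np.zeros_like(n)
    pt_sum = np.zeros((nsb, nib)) if any(t is not None for _, _, _, t in prepared) else None
    prob_sum = np.zeros((nsb, nib))
    pair_count = np.zeros((nsb, nib), dtype=np.int64)

    for ev, iv, newv, truep in prepared:
        si = np.clip(np.digitize(ev, skipped_edges, right=True) - 1, 0, nsb - 1)
        ii = np.clip(np.digitize(iv, intensity_edges) - 1, 0, nib - 1)
        flat = si * nib + ii
        n_pair = np.bincount(flat, minlength=nsb * nib).reshape(nsb, nib)
        k_pair = np.bincount(flat, weights=newv.astype(float),
                             minlength=nsb * nib).reshape(nsb, nib)
        n += n_pair
        k += k_pair.astype(np.int64)
        if pt_sum is not None and truep is not None:
            pt_sum += np.bincount(flat, weights=truep,
                                  minlength=nsb * nib).reshape(nsb, nib)
        nonzero = n_pair > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            prob_sum[nonzero] += (k_pair[nonzero] / n_pair[nonzero])
        pair_count += nonzero

    return EstablishmentArray(skipped_edges, intensity_edges, n, k, min_n,
                              pt_sum, len(pairs), prob_sum, pair_count)


# ---------------------------------------------------------------------------
# early indicator
# ---------------------------------------------------------------------------

@dataclass
class IndicatorReport:
    """Diagnostics and the 'approaching transition' flag for one flat unit."""

    years: list[int]
    mean_skipped_pct: float
    accretion: TrendFit
    mean_slope_deg: float
    slope_trend: TrendFit | None
    above_nhwl: bool
    accreting: bool
    low_slope: bool
    flagged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.flagged = self.above_nhwl and self.accreting and self.low_slope

    def to_dict(self) -> dict:
        return {
            "years": list(self.years),
            "mean_skipped_pct": self.mean_skipped_pct,
            "accretion_cm_yr": self.accretion.slope,
            "accretion_ci": [self.accretion.ci_low, self.accretion.ci_high],
            "mean_slope_deg": self.mean_slope_deg,
            "above_nhwl": self.above_nhwl,
            "accreting": self.accreting,
            "low_slope": self.low_slope,
            "flagged": self.flagged,
        }


def early_indicator_report(years: list[int],
                           dem_series: list[GridRaster],
                           exposure_series: list[GridRaster],
                           slope_series: list[GridRaster],
                           slope_threshold_deg: float = DEFAULT_SLOPE_BOUNDARY_DEG,
                           ) -> IndicatorReport:
    """Flag a flat unit as approaching a flat-to-marsh transition.

    The flag requires, over at least 3 years of elevation data: (a) the unit
    reaches above neap high water (mean skipped % > 0 in the latest year),
    (b) a positive accretion trend whose 95% CI excludes zero, and (c) a
    mean 10-m slope below the pattern-formation boundary, or a declining
    slope trend (CI excluding zero) heading toward it.
    """
    if not (len(years) == len(dem_series) == len(exposure_series) == len(slope_series)):
        raise InvalidArgumentError("years and raster series must have equal length")
    if len(years) < 3:
        raise InvalidArgumentError("at least 3 years of elevation data are required")

    # restrict all means to cells valid in every year, so annual means are comparable
    valid = np.logical_and.reduce([np.isfinite(d.values) for d in dem_series])
    if not valid.any():
        raise InsufficientDataError("no cells valid across all years")

    elev_means = [(y, float(d.values[valid].mean())) for y, d in zip(years, dem_series)]
    accretion = annual_trend(elev_means)

    slope_means = []
    for y, s in zip(years, slope_series):
        sv = s.values[valid[: s.values.shape[0], : s.values.shape[1]]
                      if s.shape == valid.shape else np.isfinite(s.values)]
        sv = sv[np.isfinite(sv)]
        slope_means.append((y, float(sv.mean())))
    slope_trend = annual_trend(slope_means) if len(slope_means) >= 2 else None

    latest_exp = exposure_series[-1].values
    mean_skipped = float(np.nanmean(latest_exp)) if np.isfinite(latest_exp).any() else 0.0
    mean_slope = slope_means[-1][1]

    above = mean_skipped > 0.0
    accreting = accretion.slope > 0 and accretion.excludes_zero and accretion.ci_low > 0
    low_slope = mean_slope < slope_threshold_deg or (
        slope_trend is not None and slope_trend.slope < 0
        and slope_trend.excludes_zero and slope_trend.ci_high < 0
    )
    return IndicatorReport(list(years), mean_skipped, accretion, mean_slope,
                           slope_trend, above, accreting, low_slope)
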