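# Methods

This note documents the models implemented in `tidalmarsh`, the parameter
choices that matter, the design decisions taken where more than one
reasonable construction existed, and what the synthetic test scenes do and
do not establish about behaviour on real data.

## Tidal exposure

The exposure of an elevation *z* is the percentage of high tides whose peak
does not exceed it:

```
skipped(z) = 100 · (1 − cycles_inundated(z) / cycles_total)
```

High tides are extracted from a gauge record as strict local maxima with an
enforced minimum separation (default 10 h, appropriate for a semidiurnal
regime with a 12.42 h M2 period); where two candidate maxima fall closer
than the separation, the higher wins. A tide *inundates* an elevation only
when its peak is strictly greater — a peak exactly at the elevation counts
as skipped — so the neap high water level (NHWL) is the lowest elevation
with skipped % > 0.

An `ExposureCurve` stores the step function exactly: its step positions are
the peak levels themselves, so evaluation at any elevation reproduces a
direct recount of the peaks, with no gridding error. Between gauge
stations the skipped percentage is interpolated linearly per elevation
along a one-dimensional estuary axis (the raster x coordinate by default);
a mixture of two step functions is again a step function on the union of
their step positions, so the interpolated curve is also represented
exactly. Outside the station range the nearest station's curve is used.
All outputs are invariant to a common datum shift of levels and elevations.

## Grid operations

Rasters are rectangular float64 grids with NaN as nodata, a semantic kind
(elevation cm, reflectance, skipped %, slope °, boolean), a cell size in
metres and an origin; files are TIFF plus a JSON georeference sidecar.

* **Slope** uses the Horn 3×3 stencil; elevation (cm) and cell size (m) are
  brought to common units before the arctangent, border cells are nodata,
  and any nodata in the stencil propagates. On an inclined plane the
  result is exact to rounding.
* **Block aggregation** over non-overlapping f×f blocks supports mean
  (any valid cell), max and sample SD (both requiring ≥ 2 valid cells,
  nodata otherwise). Trailing partial blocks are dropped.
* **Focal SD** is block aggregation with the SD reducer: the windowed
  standard deviation is computed on non-overlapping 10-m tiles, producing
  an output at tile resolution (a moving-window variant exists behind a
  flag for exploration but is not used by the analyses). The SD is
  two-pass and anchored on a member value of each block, so constant
  blocks give exactly zero.

## Micro-topography intensity and masking

The intensity of micro-topography is the within-tile sample SD of the NIR
band at 10 m. It is invariant to adding a constant to the band but not to
rescaling, so uncalibrated digital numbers are acceptable only within a
scene. A greyscale fallback band can be declared when NIR is missing; the
provenance is recorded in the raster metadata.

Before any pattern analysis three exclusions are applied, as a union:
vegetated tiles; tiles at or below NHWL (skipped % = 0), which removes the
mega-ripple zone of the lower flat; and creek tiles — cells steeper than 3°
in the 2-m slope product, block-max resampled to 10 m *and dilated by one
10-m cell*. The dilation is deliberate: the 10-m Horn slope of a tile
adjacent to an incised creek uses the creek tile's depressed mean in its
3×3 stencil, so its slope estimate is corrupted even though its own cells
are gentle; excluding the adjacent ring removes exactly the tiles whose
coordinates in the (slope, intensity) plane are unreliable. Two distinct
slope products therefore exist: the 2-m slope for creek detection and the
10-m slope for all binned analyses.

The calibration of the image metric regresses log tile-SD of NIR on log
tile-SD of slope (ordinary least squares), the slope itself coming from a
high-resolution (25 cm) elevation grid; SD of *slope* rather than SD of
elevation is used so smooth but steep surfaces are not mistaken for
patterned ones. Tiles with non-positive values are dropped and counted.

## Vegetation mapping

NDVI distributions over an estuary scene are multi-modal, with sediment
clustered low and vegetation high, but the absolute positions drift between
years with atmosphere and season. The threshold is therefore refit per
scene: a Gaussian KDE with Silverman bandwidth is evaluated on a 512-point
grid, modes are maxima with prominence at least 5 % of the peak density,
and the threshold is the arithmetic midpoint of the two most prominent
modes. Fewer than two modes raises an error (a bare scene has only the
sediment mode; the file pipeline then classifies nothing as vegetated and
records a NaN threshold in the per-scene ledger). Classification is a
strict `NDVI > threshold`; newly established vegetation between campaigns
is `late AND NOT early`, with nodata in either year propagating.

## Establishment surface

Cells at risk (valid in both years of an interval and not vegetated in the
earlier year) are binned by the earlier year's skipped % and intensity.
The skipped axis uses 101 bins: a degenerate first bin holding exactly
{0 %} — the below-NHWL class where establishment cannot occur — followed by
100 unit-width bins over (0, 100]. The intensity axis uses 85 linear bins
from 0 to the pooled 99.5th percentile. Counts are summed across intervals
before dividing (probability = Σk/Σn), which weights every observation
equally; an unweighted mean of per-interval proportions is retained as an
alternative aggregation. Bins with fewer than 30 observations are missing,
not zero.

## Trends, hypsometry, and the early-indicator flag

Annual means (elevation, skipped %) are computed over the cells valid in
every year and not vegetated at the start, then fit by OLS against year;
standard errors and 95 % t-intervals are reported from three years up.
Hypsometric curves give the percentage of above-NHWL cells equalling or
exceeding each value; slope hypsometry repeats this per tidal-position bin.
The intensity–slope relation uses 120 logarithmic slope bins between 0.01°
and 10°; empty bins are absent.

A flat unit is flagged **approaching transition** when, with at least three
years of elevation data: (a) its mean skipped % in the latest year is
positive (the unit has risen above NHWL); (b) the accretion trend is
positive with a 95 % CI excluding zero; and (c) its mean 10-m slope is
below the 0.3° pattern-formation boundary, or the slope trend is negative
with a CI excluding zero. The three diagnostics are always reported with
the flag.

## Inclined-plane drainage model

The model simulates the thin water film draining off a flat at the start of
the exposed period:

```
dW/dt = ∇ · ( K · W · ∇(W + S) )
```

with water depth W and bed elevation S in cm, cell size 1 m, and constant
dimensionless conductivity K = 1 (appropriate for very shallow films).
The bed is a ramp declining top-to-bottom by `100·cell·tan(θ)` cm per row
plus autocorrelated noise synthesised spectrally (power spectrum ∝
k^−3.4, rescaled to mean 0 and SD exactly σ_S; σ_S = 2.5 cm by default).
Lateral boundaries are plain periodic. The down-slope wrap is
offset-periodic: the ghost rows satisfy `S₀ = S_nx + (S_max + S_max/nx)`
and `S_{nx+1} = S₁ − (S_max + S_max/nx)`, and the ramp's maximum height is
defined as `S_max = nx²·d/(nx+1)` (d the per-row drop) so that this offset
equals exactly `nx·d` — the incline continues seamlessly across the wrap
and a uniform film on the noise-free ramp is an exact fixed point.

**Discretisation.** Conservative explicit finite volumes with donor-cell
(upwind) face depths: the flux across a face is `K · W_donor · ΔH / Δx`
with H = W + S and the donor the higher-H side, which prevents water
leaving an empty cell. Each donor's total outflow per step is limited to
its available water (all its outgoing fluxes are scaled by a common
factor), so W ≥ 0 holds exactly and mass is conserved to rounding. The
adaptive step is `dt = 0.2 · Δx² / (4 K max W)`; an explicit `step()` with
a user dt checks this bound and names the admissible step on violation.

**Initial condition and stop rule.** W starts uniform at W_i = 10 % of
σ_S. The run ends when the mean water-level change rate across the plane,
mean |dW|/dt, falls to 0.3 % of W_i per unit model time. The
rate form is used rather than the per-step form because the per-step
reading is coupled to the adaptive step size: as pools deepen, dt shrinks
and the per-step change falls below any fixed tolerance long before
drainage has organised (in trials at nx = 128 the per-step rule stopped
after ~75 steps with the time-averaged depth still essentially uniform).
The per-step variant remains available via `stop_rule="per_step"`.

**Outputs.** The per-cell time average of W is accumulated trapezoidally
over the whole run, including the initial transient. Its sample SD across
the grid is the *flow concentration*: ≈ 0 for sheet flow, large when water
pools or channelises. Sweeps run independent replicates on unique seeded
noise surfaces per inclination and report mean ± SE. At σ_S = 2.5 cm the
concentration declines monotonically as the inclination rises from 0.05°
to 1.5°, and at the gentlest inclination the time-averaged depth is
strongly anticorrelated with the bed noise (water sits in the lows) —
the pooling-to-sheet-flow transition that confines micro-topographic
patterning to gently sloping flats. The analyses in this package use grids
of 64–128 cells and 10 replicates per inclination, which resolve the
transition cleanly; model time is not calibrated to physical seconds, and
no sediment feedback is simulated, so the model explains where patterns can
form, not their amplitude or wavelength.

## Synthetic estuary generator

The generator produces the statistical structure the analyses assume, with
known truth, not a hydrodynamic simulation. Defaults describe a macrotidal
estuary in transition on a 520 × 800 m grid at 1 m over ten years:

* **Tides**: M2 (150 cm) + S2 (40 cm) in phase at t = 0, 35 days at
  10-minute sampling, Gaussian noise SD 5 cm, three stations whose
  amplitude grows linearly along the axis (factors 1.0–1.2) — a spring–neap
  envelope with along-estuary amplification.
* **Profile**: a gently sloping anterior flat (0.25 cm/m ≈ 0.14°, crest
  210 cm) over a logistic shoulder dropping 4 m to the channel — the
  convex, flat-topped profile that accretion produces. The flat accretes
  2 cm/yr uniformly (tapering to zero below datum).
* **Ridge–runnel texture**: an anisotropic sinusoid (wavelength 3 m,
  relief 8 cm, inside the ≤ 10 cm envelope) modulated by smooth spectral
  noise, planted only where the pre-texture slope is below 0.3° and the bed
  is above NHWL, growing as the flat rises and fading quadratically toward
  the slope ceiling (patterns weaken near their boundary). Mega-ripples
  (18 m, 20 cm) are added below the zero-exposure elevation; three
  meandering creeks are incised 40 cm with compact super-Gaussian
  cross-sections whose banks exceed the 3° cutoff at 2 m.
* **Orthophotos**: NIR = 0.35 + 0.01 per cm of micro-relief residual (the
  DEM minus its 3-m Gaussian smooth, saturating at ±4 cm), minus 0.05 in
  pooled sub-NHWL micro-lows, plus sensor noise (SD 0.005); Red = 0.82·NIR
  for sediment. Vegetated tiles render NIR ≈ 0.55, Red ≈ 0.12, giving an
  NDVI mode well above the sediment mode. Windowed NIR variance therefore
  rises exactly where texture was planted.
* **Vegetation**: per 10-m tile and campaign interval, establishment is an
  independent Bernoulli draw with p = logistic(−10 + 0.08·skipped% +
  80·intensity), forced to zero where skipped % = 0; vegetation persists.
  The drivers are the *measured* exposure and intensity of the earlier
  year, so the recorded per-tile p is exactly the quantity the
  establishment surface estimates. Over ten years the default scene moves
  from 0 % to ≈ 10 % vegetated.

All randomness flows from one root seed through named substreams (tides,
DEM, creeks, per-year ortho, per-interval vegetation), so identical
configurations are bit-identical and individual stages can be re-run in
isolation.

The demo's indicator scenario uses two reduced flats (200 × 300 m, ten
years): an accreting one whose crest starts just below NHWL (106 cm) and
rises 3 cm/yr at slope ≈ 0.1°, with a deliberately conservative logistic
(intercept −14, skipped coefficient 0.6) so establishment is vanishingly
unlikely until the flat sits well above NHWL; and a static 1° control.
Across seeds the accreting flat is flagged in year 2–3 and first vegetates
around year 6–8, a 4–5 year lead; the control is never flagged.

**What the synthetic tests do not show.** The generator writes the
assumed monotone logistic dependence into the truth, so recovery tests
validate the *estimation machinery* (binning, masking, counting,
exclusion rules), not the ecological claim itself; they also cannot test
datum errors, georeferencing problems, atmospheric variation beyond a
per-scene NDVI shift, macroalgae that mimic vegetation NDVI, or wave- and
current-driven morphology. Real-data use still requires the calibration
step against high-resolution elevation and per-scene threshold
diagnostics.

## Numerical choices and edge cases

* Sample SD (n − 1) throughout; blocks with < 2 valid cells are nodata.
* A high tide exactly equal to an elevation does not inundate it
  (strict >), making the NHWL definition sharp.
* Peak separation uses highest-first precedence; tie heights are resolved
  by scan order (continuous level noise makes exact ties improbable).
* The mean skipped-% and skipped-fraction tabulations use the identical
  floating-point expression (100·k/n), so curve evaluation and direct
  recounts agree bit-for-bit.
* KDE threshold fitting subsamples above 50 000 values (deterministically)
  and reports bandwidth, mode count and prominences as diagnostics.
* OLS trend CIs use the t distribution with n − 2 degrees of freedom; with
  two years the slope is reported without a standard error.
* Establishment bins use right-closed skipped intervals so that 0 % falls
  only in the degenerate first bin.
* Classification accuracy at a midpoint threshold is bounded by the mixture
  overlap: two equal Gaussian modes 4 SD apart cannot exceed ≈ 97.7 %
  accuracy; above 99 % requires ≈ 6 SD or more of separation (the default
  synthetic scene uses ≈ 8 SD).

## Known limitations

* The intensity metric is scale-dependent; cross-scene comparisons need
  radiometrically consistent imagery or the provided calibration.
* The drainage model has no erosion–deposition feedback and therefore does
  not explain the observed *decrease* of pattern intensity at near-zero
  slopes, only the upper slope boundary.
* The 1-D along-axis interpolation of exposure assumes the estuary axis is
  aligned with a raster coordinate; no reprojection is provided.
* Flat "units" for the indicator are whole scenes (or caller-cropped
  rasters); polygon zonation is left to the caller.
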