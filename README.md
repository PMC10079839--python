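# tidalmarsh

Early indicators of tidal-flat-to-marsh transitions.

Estuarine tidal flats can shift, over just a few years, from bare sediment
to vegetated marsh — a transition between alternative stable states that is
hard to reverse and reshapes flood safety, bird habitat and carbon budgets.
Before pioneer plants appear, two slower changes prepare the ground: the
upper flat accretes sediment (rising 1–3 cm per year in heavily dredged
European estuaries) and flattens, and metre-scale *micro-topographic*
ridge–runnel patterns (vertical relief ≲ 10 cm) develop on the gently
sloping, frequently exposed parts of the flat. These patterns precede and
facilitate seedling establishment, which makes them usable as an early
warning signal.

`tidalmarsh` implements that analysis chain as a tested Python library plus
CLI, aimed at coastal scientists working with public lidar, orthophoto and
tide-gauge archives:

* **Tidal exposure** — the fraction of *skipped* tidal inundations at
  elevation *z*,

  `skipped(z) = (1 − cycles_inundated(z) / cycles_total) · 100 %`,

  computed from high-tide peaks of gauge records and interpolated along the
  estuary axis. Elevations below neap high water (NHWL) skip 0 %.
* **Micro-topography intensity** — the sample SD of the near-infrared band
  in 10 × 10 m tiles of false-colour orthophotos, a proxy for cm-scale
  relief that lidar often cannot resolve, with an exclusion mask for
  vegetation, sub-NHWL mega-ripples and tidal creeks (slope > 3° at 2 m),
  and a log–log calibration against slope variability from high-resolution
  elevation data.
* **Vegetation mapping** — NDVI = (NIR − Red)/(NIR + Red) with a per-scene
  threshold placed midway between the sediment and vegetation density
  modes.
* **Establishment surface** — the probability of new vegetation
  establishment in a 101 × 85 grid of (skipped %, intensity) bins, pooled
  over campaign intervals; bins with n < 30 are suppressed.
* **Drainage model** — an inclined-plane nonlinear-diffusion simulation,
  `dW/dt = ∇·(K W ∇(W+S))` with K = 1, of a thin water film draining over a
  tilted bed with autocorrelated noise (SD 2.5 cm), using an offset-periodic
  down-slope boundary. The SD across the grid of the time-averaged water
  depth (*flow concentration*) falls from pooling/channelled drainage to
  sheet flow as the incline steepens from 0 to 1.5°, explaining why patterns
  form only below ≈ 0.3°.
* **Early indicator** — a flat unit is flagged *approaching transition*
  when it lies above NHWL, shows a positive accretion trend (95 % CI
  excluding zero), and its mean 10-m slope is below (or declining toward)
  the 0.3° pattern boundary.
* **Synthetic estuary generator** — tides, accreting convex DEMs with
  ridge–runnel texture, creeks and mega-ripples, rendered orthophotos, and
  stochastic logistic vegetation dynamics with full ground truth, so every
  stage is testable offline.

## Worked example

Exposure curves for a three-station synthetic estuary (amplitude grows
along the axis):

```python
from tidalmarsh import SynthConfig, gen_tide_series, exposure_curve

cfg = SynthConfig(seed=0)
curves = [exposure_curve(s) for s in gen_tide_series(cfg)]
for s, c in zip(gen_tide_series(cfg), curves):
    print(s.station, c.n_cycles_total, float(c.evaluate(150.0)))
```

prints (station, high-tide count over the 35-day record, and the skipped
fraction at 150 cm):

```
S0 at x=0 m:   68 high tides, NHWL=112.4 cm, spring HW=201.1 cm -> 39.7 %
S1 at x=400 m: 68 high tides, NHWL=123.1 cm, spring HW=214.8 cm -> 25.0 %
S2 at x=800 m: 68 high tides, NHWL=135.5 cm, spring HW=239.2 cm -> 19.1 %
```

A 150-cm flat skips 40 % of inundations near the mouth but only 19 % at the
amplified inner station — the same elevation sits lower in the tidal frame
where the tidal range is larger.

The drainage sweep from the CLI:

```sh
tidalmarsh sweep --nx 64 --reps 5 --seed 0 --inclinations 0.05,0.5,1.5 --out sweep.csv
```

```
 inclination_deg  mean_concentration       se  n
            0.05            0.373722 0.005807  5
            0.50            0.333744 0.016877  5
            1.50            0.220100 0.009503  5
```

Flow concentration (cm) falls by 40 % between a 0.05° and a 1.5° incline:
on the near-flat plane the draining film pools in the topographic lows,
while on the steep plane it spreads into uniform sheet flow.

`tidalmarsh demo --seed 0 --out demo/` runs the full chain on a seeded
synthetic estuary and two scenario flats; in the demo report the accreting,
flattening flat is flagged at year 3 while its first vegetation
establishment occurs in year 8 — a five-year early warning — and the static
1° control flat is never flagged.

## Layout

```
src/tidalmarsh/
  tides.py        skipped-inundation metrics and exposure curves
  raster.py       GridRaster container, Horn slope, block/focal statistics
  vegetation.py   NDVI, bimodal thresholds, change detection
  microtopo.py    intensity metric, exclusion mask, calibration
  indicators.py   hypsometry, trends, establishment surface, the flag
  drainage.py     inclined-plane drainage model and inclination sweeps
  synth.py        synthetic estuary generator with ground truth
  pipeline.py     orchestration, file manifests, demo
  cli.py          `tidalmarsh` command-line interface
```

See `docs/methods.md` for the underlying models, parameter choices and
limitations.
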