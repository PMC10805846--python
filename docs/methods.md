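# Methods

This note documents the models, procedures, and numerical choices behind the
`understory` package: a pipeline from 15-minute microclimate logger records
and gridded predictors to monthly understory temperature surfaces, thermal
traits, geostatistical heterogeneity measures, and spatial model diagnostics.

## Harmonization of logger records

Raw records are 15-minute air-temperature samples in UTC. They are averaged
into clock hours (hours without samples stay missing; no imputation), shifted
to local solar time by a whole-hour offset `round(lon / 15)` (rounding half
away from zero; no political time zones, so the same rule can be applied to
gridded macroclimate), and reduced per calendar month to three responses:

* `T_daily` — mean over all hourly records,
* `T_dt` — mean over local hours [06:00, 18:00) (half-open, so day and night
  partition the 24 h exactly),
* `T_nt` — mean over the complementary hours.

With complete coverage the identity `T_daily = (T_dt + T_nt) / 2` holds
exactly, which the tests verify. Months are never dropped silently: a
`coverage` fraction (hours present / hours expected) is reported and months
below a threshold (default 0.9) or missing either window entirely are flagged
invalid. Month membership follows the *local* timestamp.

## Predictors and the training table

Nine logical predictors: elevation, slope, aspect, LAI, FAPAR, canopy height,
and three macroclimate variables (2-m air temperature, precipitation, net
solar radiation). Rasters of differing resolution are harmonized by nearest
neighbour only — values are never interpolated, so categorical-like layers
stay categorical. Macroclimate enters at its native coarse cell, expanded by
nearest neighbour. The macroclimate temperature predictor is a per-calendar-
month climatology reduced with the same local-time windows as the logger
data, each year weighted equally. Cells with tree canopy cover below 40 %
(inclusive threshold: a 40.0 % cell is forest) are masked as non-forest, and
sensors on masked cells are excluded with a logged count.

Aspect is circular, so it enters design matrices as (sin, cos); it still
counts as a single predictor when interpreting the feature-subsampling
hyperparameter, which is mapped onto the 10 internal columns by proportional
rounding.

## Bagged regression-tree ensemble

The response (one model per time scale) is fit by bootstrap aggregating of
CART regression trees: each learner sees an n-out-of-n bootstrap resample;
at each split a random subset of predictors is considered (the common
random-forest variant of per-split subsampling; per-learner subsampling was
the design alternative and was not taken because the per-split form is what
mainstream bagged-tree implementations do); the ensemble prediction is the
unweighted mean over learners. Trees have no depth cap other than the
minimum leaf size. Three hyperparameters are tunable — minimum leaf size
(2–8), number of learners (10–500), number of predictors sampled (1–8) —
over a default lattice {2,4,6,8} × {10,50,100,200,500} × {1..8}, scored by
mean RMSE under a 5-fold cross-validation whose seed-determined partition is
reused at every grid point (exact ties: first point wins). The backing
implementation is scikit-learn's `RandomForestRegressor`, which is exactly
this estimator; all randomness derives from a single integer seed and fits
are bit-reproducible.

Diagnostics are defined operationally and implemented in-package:
permutation importance is the raw increase in training RMSE when one
predictor column (both aspect components jointly) is permuted, averaged over
repeats and *not* floored at zero; partial dependence at a grid value is the
mean prediction over the training rows with that predictor clamped.

## Thermal traits and zones

`ΔT = T_under − T_open` (negative ⇒ understory cooler) and
`R_T = T_dt − T_nt` are elementwise raster differences with no-data
propagation, after nearest-neighbour alignment. For stratified summaries the
tropics are partitioned into 18 zones: elevation bands [0, 500), [500, 1000),
[1000, ∞) m crossed with latitude bands [0°, 5°), [5°, 10°), [10°, 23.45°]
per hemisphere. All bands are lower-inclusive (the printed ranges overlap at
their boundaries, so a convention had to be fixed to make the partition
testable), and lat = 0 is assigned to the Northern classes (arbitrary but
fixed). Zonal tables report plain cell means ± sd; an area weighting by
cos(latitude) is available but off by default, since at tropical latitudes
within a 5°-wide band the cell-area variation is below 1.5 %.

## Semivariogram heterogeneity

For each temperature surface: (1) detrend by subtracting the OLS plane
`T = β0 + β1·lat + β2·lon` (plane only — no quadratic or interaction terms);
(2) compute the directional empirical semivariogram
`γ(h) = Σ(z_i − z_j)² / 2N` over point pairs binned by great-circle
(haversine) lag, keeping pairs whose bearing lies within an angular
tolerance (default ±22.5°) of the chosen direction modulo 180°; (3) fit
`γ(h) = c0 + c1·(1 − exp(−h/a))` by least squares weighted by pair counts,
parameters bounded non-negative. The **sill** is `c0 + c1`; the
**minimum distance** `d` is the practical range where the fitted curve
reaches 95 % of the sill, `d = a·ln(c1 / 0.05(c0+c1))` (≈ 3a without a
nugget). The asymptotic exponential model has no finite lag of "maximum
semivariance", so the 95 % convention — standard in geostatistics and
monotone in `a` — is used and documented as this package's definition. A
pure-nugget fit (`c1 ≤ 0.05·sill`) has no defined `d` and reports `None`
rather than a number.

Comparing understory and open-air surfaces with identical settings
(east–west direction, 10 km analysis resolution by block-mean coarsening,
400 km maximum lag at full scale; smaller lags on desk-scale grids) yields
`d_under`, `d_open` and their ratio; fine-scale structure in the understory
surface drives `d_under < d_open`.

## Spatial model assessment

**Degree of interpolation.** Training rows are standardized (training mean
and sd) and a PCA is fitted *on the training rows only* — fitting on
prediction pixels would leak the prediction domain into its own
applicability measure. The retained axis count k is the smallest whose
cumulative explained variance reaches a threshold (default 0.93), not a
hard-coded 6 — six axes is a property of one particular dataset. For each
of the C(k, 2) unordered axis pairs (15 when k = 6) the convex hull of the
training points is built in that 2-D space; a pixel scores 1 inside (the
boundary counts as inside, with a small scale-relative tolerance on the
half-plane tests so training points score exactly 1) and 0 outside; the
degree of interpolation is the mean over pairs. Degenerate pair spaces
(collinear training points) fall back to bounding-segment membership with a
log message. Monthly maps are averaged per cell into an annual map.

**Buffered spatial leave-one-out CV.** Each sensor in turn is held out; the
ensemble is retrained with *fixed* hyperparameters (the procedure retrains,
it does not re-tune; nested tuning is available as an option) on all sensors
strictly farther than the buffer radius, and the held-out sensor's months
are predicted. Radius 0 is ordinary leave-one-sensor-out. RMSE, bias, R² and
mean training size are pooled per radius; a stabilization radius is the
smallest radius where RMSE changes by less than 5 % (configurable) from the
previous one.

## The synthetic world

The generator supplies every input with known ground truth. True understory
temperature is deliberately *linear in the predictors*:

```
T_true(t) = macro_t(month, local hour)
          + base_offset
          + lapse_rate · elevation/1000
          − canopy_damping · LAI · (macro diurnal deviation)
          + night_warming · FAPAR · 1[night]
```

Defaults: lapse −6.5 °C km⁻¹, damping 0.05 per LAI unit, night warming
0.5 °C at FAPAR = 1, base offset −1.0 °C, white 15-min noise 0.3 °C,
correlated monthly noise sill 0.25 °C² with 50 km range. All are
configuration, not hard-coded: the lapse rate is the standard environmental
value, the damping and night-warming terms encode the canopy mechanisms
(shortwave interception by day, longwave retention by night) at magnitudes
that put the simulated offset and range reduction in the low single-digit
°C range typical of closed-canopy forests, and the base offset makes the
mean daily offset negative — the qualitative direction the pipeline must
report. Monthly means of the truth are exactly
`macro_T + base_offset + lapse·elev/1000 + ½·night_warming·FAPAR` for the
daily scale, giving parameter-recovery tests a closed-form target.

Observed records add two noise sources chosen to mimic weather vs.
instrument error: a Gaussian random field drawn once per month (exponential
covariance, simulated by circulant embedding with eigenvalue clipping and a
variance-restoring rescale; the semivariogram of a field with e-folding
range `a` has practical range 3a) and white noise per 15-min sample, which
averages to near zero in monthly means. Terrain is multi-octave smoothed
noise; slope and aspect derive from its metric gradient; LAI, FAPAR and
canopy height are correlated smooth fields; tree canopy cover is calibrated
so that an exact, configurable fraction of cells (default 0.8) passes the
40 % forest threshold. Macroclimate lives on a coarser native lattice
(factor 5) with a 14:00-local diurnal peak — inside the day window, so
`R_T > 0` on noiseless data — and a hemisphere-phased seasonal cycle.

A `roughness` parameter divides all field correlation scales. It exists for
the buffered-CV experiments: the "autocorrelation" arm uses the default
smooth landscape with mesoscale (30 km) noise, where excluding neighbours
inside a 60 km buffer removes exactly the sensors whose shared weather
inflates apparent accuracy; the i.i.d. control arm uses a rough landscape
(roughness 16) whose predictors and noise both decorrelate below the sensor
spacing, so the buffer removes an effectively random ~9 % of training rows
and RMSE stays flat up to that small training-size effect. On a smooth
landscape even i.i.d. noise shows some radius dependence, because buffering
then also removes predictor-space neighbours — a genuine property of
spatially structured predictors, not an artefact, and the reason the control
must be run on an unstructured world.

What the generator does **not** emulate: real SRTM/CGLS/GEDI marginal
statistics, cloud and QA artefacts, sensor drift, soil or surface
temperature channels, interannual macroclimate variability, and non-linear
predictor interactions beyond the damping product. Passing recovery tests
therefore demonstrates the pipeline's correctness and its behaviour under
known spatial structure — not field accuracy on real satellite inputs.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale worlds — 1°–3° blocks at
0.01°–0.03° cells, 30–150 sensors, 2–6 months — sized so the full suite
completes in minutes while every estimator still has enough data (900-row
training tables for recovery, 20-seed Monte-Carlo for geostatistics,
10-seed frequency checks for behavioural contrasts). Variogram fits start
from data-driven initial values and are bounded non-negative; hull
membership uses a 1e-9 scale-relative tolerance; zero-variance predictors
are dropped from PC spaces with a warning; coarsening ignores no-data cells.
Raster I/O uses ESRI ASCII grids (plain text, WGS84 lat/lon, explicit
no-data) and all distances are haversine — the study domain spans
continents, so no single projected CRS is appropriate.

## Known limitations

* Monthly LAI/FAPAR are treated as static composites; per-month rasters are
  accepted but the synthetic generator does not vary them seasonally.
* The variogram analysis is single-direction; anisotropy beyond the angular
  window is not modelled, and no kriging is performed from the fit.
* The degree-of-interpolation measure is hull-based only; density-based
  applicability measures are out of scope.
* The local-time rule is purely longitudinal; countries whose civil time
  deviates far from solar time will differ from logger clocks set to local
  civil time.
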