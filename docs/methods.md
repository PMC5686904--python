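# Methods

This note documents the models and numerical choices behind `tickdyn`: what
the synthetic study system emulates, how the time-aware regression is
defined, and where the design was genuinely open.

## The synthetic study system

The package targets a monitoring design in which trained volunteers drag a
1 m² cloth along two fixed 100 m transects per forest site, once a month,
and count the nymphal ticks caught questing (the AQT count). Because such
volunteer collections are typically not publicly deposited, all inputs are
generated by `tickdyn.synthetic` with known ground truth. The generator is
a study design, not a geography: it reproduces the *statistical* character
of the data — a small, weather-uniform country; zero-heavy, over-dispersed
counts; smooth vegetation seasons — without mimicking any real map.

**Landscape.** A `grid_shape` raster of 500 m cells (default 60 × 60).
Land cover is drawn as a patchwork of 30 synthetic source-legend codes at
the cell level, upsampled to 25 m native pixels with 15 % salt noise, then
reclassified to a 12-class legend (three forest classes, grassland,
heathland, bushland, agriculture, urban, water, dunes, wetland, other —
the source legend never enumerates its reduced classes, so this set is the
package's own choice) and majority-resampled to 500 m and 1 km. Each
transect's cell is forced to a deciduous source class so every monitored
transect sits in forest.

**Weather.** Five observed daily variables (minimum/maximum temperature
via a midpoint-plus-range construction, precipitation, Makkink-style
reference evapotranspiration, relative humidity). Each follows an annual
sinusoid (period 365.25 d) plus a regional AR(1) anomaly shared by all
sites, a static spatial gradient across the grid (about 1.5 °C, 5 % RH,
0.35 mm/d ET span — deliberately small, as fits a flat, maritime country),
and a small per-site AR(1) microclimate term. Physical bounds are enforced
after summation (RH ∈ (0, 100], precipitation ≥ 0, tmin ≤ tmax). The two
humidity derivatives — saturation deficit and vapour pressure — are never
generated; they are always derived downstream (see below), so generator
and feature pipeline cannot drift apart.

**Vegetation.** NDVI/EVI/NDWI as 8-day composites: a regional seasonal
curve plus a static per-pixel level offset (gradient + smooth noise),
clipped to [−1, 1]. This mirrors composite products in which temporal
overlap smooths the signal; it deliberately omits clouds, gaps and
snow-contaminated winters.

**Counts.** For transect *t* sampled on day *d* (one uniformly drawn day
per site-month; both transects of a site share the day):

    log mu = b0 + b1 * cos(2*pi*(doy - 150)/365.25) + sum_k w_k * z_k(t, d)

with b0 = 3.0, b1 = 1.0 (peak activity late May), and z_k the standardized
anomaly of weather driver k — the site's window mean minus the regional
seasonal expectation, scaled to unit variance across the sample. The
anomaly keeps the site's static weather offset: a persistently wetter site
is genuinely more active, and with multi-year windows a purely temporal
anomaly would collapse to one value per year and alias the mast scores.
Counts are negative binomial with size k = 6 (variance mu + mu²/6), then
masked to zero with independent probability 0.33. Defaults
(`driver_weights = {"ev-365": 0.6, "rh-30": 0.45}`, b0, k) were fixed once
so that the overall zero fraction lands near the one-third rate and the
occasional-peak character of real volunteer counts; the default 15 sites ×
2 transects × 108 months give 3240 observations.

What passing tests on this world do **not** show about real data: there is
no observer effort variation, no missed visits, no wildlife/host dynamics,
no spatially structured habitat quality, and the drivers really are the
configured weather anomalies — real AQT drivers are contested.

## Dataset variants

Zeros and peaks are the two noise pathologies examined. The *reduced*
variants drop every zero count inside the tick season (March 1 – October
31, inclusive) and a seeded uniform half (⌊0.5·n⌋, without replacement) of
the out-of-season zeros. The *smooth* variants apply a Savitzky–Golay
filter per transect, treating the monthly samples as equally spaced by
index — sampling is nominally monthly, and index spacing avoids bespoke
irregular-grid machinery. Window 5 / order 2 is the smallest window that
suppresses single-month spikes while preserving the spring–autumn
bimodality; edge points use the filter's terminal polynomial fit, and
results are floored at 0 (negative counts are meaningless). Filtering
always precedes smoothing. Sequences shorter than the window are passed
through unchanged with a warning.

## Feature engineering

101 predictors per observation, in five blocks (6 habitat + 9 mast + 77
weather + 6 vegetation + 3 land cover); dropping the transect-only habitat
and mast blocks leaves the 86 country-level features.

* **Weather (77).** Seven variables × eleven windows {1–7, 14, 30, 90,
  365} days. A window-*w* feature is the arithmetic mean over the *w* days
  strictly *before* the sampling date — today's count reflects past
  conditions, so the sampling day itself is excluded. Saturation deficit
  and vapour pressure come from the Magnus formula over water,
  e_s(T) = 6.112 exp(17.62 T / (243.12 + T)) hPa at the daily midpoint
  temperature; vp = (rh/100)·e_s, sd = e_s − vp, so sd + vp ≡ e_s exactly
  (a conservation identity the tests exploit). The name `vp` denotes
  vapour pressure; the deficit lives in `sd`.
* **Vegetation (6).** Composites are averaged per calendar month and the
  monthly series decomposed additively (period 12, moving-average trend)
  into trend + seasonal + residual. Two summaries per index: the seasonal
  minimum placed back on the series' mean level (so `min_ndvi` is an NDVI
  value, not a centred anomaly) and the seasonal range (max − min of the
  seasonal component). They are computed once per location from the full
  multi-year series and are static within the study.
* **Land cover (3).** The 12-class value at the 25 m pixel, the 500 m
  cell, and the 1 km cell. Majority resampling breaks ties to the smallest
  class code (deterministic and order-independent); nodata cells do not
  vote. Categorical features are carried as integer codes, not one-hot —
  tree ensembles split on code thresholds, and the 101-column accounting
  stays exact.
* **Mast (9).** Ordinal 0–5 scores for oak, American oak and beech at lags
  0–2 years.

Assembly fails loudly rather than imputing: any observation an input does
not cover raises an error naming the observation and feature.

## Time-aware regression

Random forests are not time-aware; trained on raw counts they mostly learn
the seasonal cycle. The target is therefore transformed into monthly
Z-scores. Counts are pooled per calendar month across all sites and years
(per-site months would hold only ~9 values — too few to trim); values
strictly outside the inter-quartile range [Q1, Q3] (linear-interpolation
quantiles, the default of mainstream numerical stacks, pinned so tests are
exact) are discarded, and the survivors' mean and sample standard
deviation define z = (y − μ_m)/σ_m. Degenerate months (fewer than two
survivors, or zero variance) fall back to σ = 1 with a warning. Trimmed
observations are excluded only from μ/σ estimation, not from training.

The learner is scikit-learn's `RandomForestRegressor` (500 trees, ⅓ of
features per split, unlimited depth — standard regression-forest settings;
no hyperparameter search). Protocol: one seeded 70/30 split; ten fits
differing only in the forest seed; error metrics and MSE-reduction
importances (normalised to sum to 1) averaged across fits. RMSE and NRMSE
are computed after de-normalising predictions and truth *without*
clipping, so the clamp cannot bias the error; NRMSE divides by the
observed range of the de-normalised test truth (the denominator is not
fixed by convention; range-normalisation is documented, not asserted as
canonical). Per-transect R² is reported with bins 0.7 < R² < 1
(moderate-to-strong) and 0.3 < R² < 0.7 (weak-to-moderate); transects with
fewer than three test rows get an undefined R². Clipping at zero is
applied only on the mapping path.

`TimeAwareForestRegressor` packages transform + forest as a sklearn
estimator (the month column of X feeds the transform and is excluded from
the predictors), composing with pipelines and `clone`.

## Experiments

*Variant comparison* runs the full protocol on each of the four variants
and selects the lexicographically smallest (RMSE, NRMSE) — the tie rule is
the package's own. *Multi-scale importance* refits the selected dataset
once per temporal scale on 31 features (the 24 non-weather features plus
that scale's 7 weather aggregates), reusing the same split for
comparability across scales, and also reports the full 101-feature model's
top 10. Display importances are ×100, rounded half-even to natural
numbers.

A caveat the synthetic truth makes measurable: impurity importances on
correlated meteorology do not isolate the causal feature. The configured
ev-365 driver is recovered cleanly, but the rh-30 driver's importance is
shared across the humidity family (rh-365, sd-365, vp-30) — saturation
deficit, being derived from rh and temperature, is a particularly
effective joint proxy. Under a *null* world (all driver weights zero)
importances are not uniform either: split mass concentrates on the
continuous predictors, and long-window aggregates — whose spatial offset
dwarfs their temporal variance — act as site fingerprints absorbing
spurious site-level fits. Rankings should be read as families of
correlated drivers, not single causes.

## Mapping

Forest pixels are the three forest classes of the 12-class map (mixed
forest included; monitoring sites sit in deciduous or mixed stands). The
86-feature model is retrained on the *full* dataset (train + test) — the
mapped year is wholly out of the training target's support anyway — and
predicts every day of the target calendar year (365 days, 366 in leap
years). De-normalisation uses the prediction date's calendar month and
clips at zero. Products: per-pixel annual mean and population standard
deviation, optional single-date rasters (a requested date's raster equals
the corresponding slice of the daily stack exactly), and daily profiles at
the site pixels alongside the long-term monthly means μ_m. Pixel weather
comes from the regional field plus gradient (site microclimate noise is
not extrapolated); pixel vegetation summaries use the generator's additive
structure, with an explicit per-pixel decomposition wherever the [−1, 1]
clip binds. Rasters are ESRI ASCII grids with nodata −9999 outside the
forest mask.

## Problem sizes and tolerances

The test suite runs compact studies (typically 6 sites × 4 years,
12 × 12 grids, 30–100 trees) chosen so the full suite completes in a few
minutes; seed-averaged properties (driver recovery) use five default-scale
worlds at 100 trees × 3 runs. `scripts/acceptance.py` runs the default
3240-observation study with 100-tree forests and the full ten repeated
runs — importance normalisation is invariant to ensemble size. Exact
identities (importance sums, Z-score round-trips) are asserted at 1e-9;
stochastic properties are asserted at the qualitative level (orderings,
sign of rank correlations) rather than with numeric tolerances.

## Known limitations

* The generator's drivers act through weather anomalies with a static
  site component; it cannot express habitat-mediated effect modification.
* Monthly Z-scores assume the monthly pooled distribution is stable across
  years; a trend in tick abundance would leak into the residuals.
* Savitzky–Golay smoothing across missing months treats gaps as unit
  steps; with many dropouts the effective window widens in calendar time.
* Impurity-based importance is biased toward high-cardinality continuous
  predictors; see the caveat above.
* The country maps extrapolate a model trained at a handful of forest
  sites to all forest pixels; nothing in the synthetic tests validates
  such transfer for real data.
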