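# Methods

This note documents the models, conventions and design choices behind
carbonscape, in the spirit of a model-description appendix: what each
stage assumes, which knobs matter, and what the synthetic tests do and do
not demonstrate about real data.

## Plot-level carbon accounting

Individual tree biomass uses organ-wise power laws `W = a·(D²H)^b` with
D in cm, H in m and W in kg. The shipped registry carries published
coefficients for *Populus*, *Salix*, *Pinus tabuliformis*, *Ulmus pumila*
and *Pinus sylvestris* var. *mongholica*, each with its carbon
coefficient (0.41–0.50). Units are a convention choice: the source
tables print no units, and cm²·m is the convention under which the
coefficients yield plausible stem masses (a 20 cm/10 m poplar trunk
evaluates to ≈65.5 kg).

Shrub biomass uses whole-plant forms driven by crown width M (m) and
height H (m): a power law in crown volume or a quadratic polynomial in
H·M. Two caveats are deliberate:

- The crown volume convention is the ellipsoid `V = (π/6)·M²·H`. The
  source material never defines V; the convention is configurable
  (`volume_fn` argument).
- The shrub coefficient sets shipped in `default_registry()` are
  **placeholder repairs**: the available printed forms are
  typographically corrupted (an impossible exponent, a missing operator).
  The power-law exponent is repaired to b = 1.06 and the polynomial keeps
  the printed digit groups as (c0, c1, c2). They are flagged in the
  docstring and must be replaced from an authoritative source before real
  use; every coefficient lives in config for exactly this reason.

Herb carbon is the quadrat mean of (above + below dry mass) × carbon
coefficient per m². The herb carbon coefficient defaults to 0.45 and is
configurable — the governing measurement guideline is cited in the
source material without a printed value. Plot density (t/ha) = woody
kg C / 1000 / plot area (ha) + 10 × herb kg C/m²; the factor 10 is the
m²→ha unit conversion.

Unknown species raise by name unless a fallback model is supplied,
mirroring the field practice of substituting a similar species' rates.

## Vegetation indices

Two band layouts are supported: a Sentinel-2A-like 10 m layout (b2, b3,
b4, b5, b8, b8A) and a Landsat-8-OLI-like 30 m layout (b3, b4, b5).
Formulas are the standard published ones. Three conventions to note:

- SAVI's soil factor defaults to L = 0.5 (configurable per call). On the
  3-band coarse layout SAVI uses the NIR/red pair (b5, b4); a circulated
  variant written with a panchromatic band is treated as a typo.
- The coarse layout has no blue band, so its EVI is the two-band EVI2
  form; gCI and NDWI use their standard definitions.
- Pixels are areas: north-up grids, origin top-left, half-open pixel
  squares, and all point lookups are containment-based (no
  interpolation). Zero-denominator pixels are masked, never infinite.

## Predictor screening

Pearson r uses the product-moment formula; constant vectors are an error
rather than r = 0. The selection threshold applies to |r| (default 0.5)
with an optional top-k fallback so a selection always exists — observed
workflows keep indices with |r| below nominal thresholds, so the
threshold/fallback pair is configurable rather than hard-coded. VIF
removal is iterative worst-first until all VIF ≤ limit (default 10);
exact collinearity removes the later-registered column. Rows with any
missing value are dropped listwise first.

## Density models and metrics

The three families are OLS (written out, with an explicit rank check),
and scikit-learn's RandomForestRegressor / DecisionTreeRegressor pinned
to n_estimators = 100, max_depth = 5, min_samples_split = 3,
random_state = 42 (forest) and max_depth = 4, min_samples_split = 3,
random_state = 42 (tree). Data split is a seeded simple random 7:3
(⌈0.7n⌉ train). Metrics follow the definitions in the README; two
conventions are deliberate:

- rRMSE = RMSE/ȳ. A printed variant sqrt(MSE/ȳ) circulates but is
  dimensionally inconsistent with reported rRMSE magnitudes
  (≈ RMSE/mean); the variant is available behind `as_printed=True`.
- MBE = mean(observed − predicted): positive MBE means underprediction.

Negative density predictions are floored at 0 in maps (physical
constraint) with the floored count reported, but left raw inside metric
computations.

## Cross-resolution transfer

The 10 m grid must exactly nest the 30 m grid (3×3, shared origin).
Aggregation takes each 30 m cell as the arithmetic mean over its 10 m
*forest* children and records the forest fraction; weighting cell areas
by that fraction makes the coarse total equal the fine total to floating
precision (the conservation test asserts 1e-6 relative). Nearest-neighbor
aggregation is not offered; mean aggregation is the stated convention.

Approach 2 trains only on cells with forest fraction ≥ 0.5 (default) to
limit mixed-pixel dilution, optionally subsampled to `sample_n` cells
per seed, and predicts over every cell with any forest child. The
reference cells are the sole training target; plot measurements enter
Approach 2 only upstream, through the fine-scale per-class models.

Discrepancy classes use |est − ref|/ref with closed-interval boundaries:
exactly 30% and exactly 60% are both "moderate" (the verbal definition
"between 30 and 60%" is ambiguous at its endpoints; the closed interval
is the documented choice). Zero-reference pixels are excluded and
counted.

## Land-use classification

Per-class Gaussian models (sample mean, sample covariance, equal priors
by default); singular covariances receive an escalating diagonal ridge
starting at 1e-8·trace/d and the regularisation is reported. Ties in
the posterior go to the lowest class label. Accuracy is OA = trace/n and
Cohen's κ from the confusion marginals. The synthetic legend has six
classes (cropland, forest, shrub, grassland, water, other); "other"
completes a published five-name legend described as six-class.

## Geodetector

`q = 1 − Σ n_h σ_h²/(n σ²)` (population variances; the ANOVA identity
makes q the between-stratum variance share). Strata with fewer than two
observations are excluded and reported rather than entering with zero
variance. Interaction categories follow the standard five-way comparison
of q(A∩B) with q(A), q(B), min, max and q(A)+q(B), with a 1e-9 equality
tolerance. No significance test is attached. Continuous covariates are
stratified by quantile or equal-interval bins; empty bins are merged
with a warning.

## Synthetic scene generator

The generator emulates the study conditions, not any particular scene:

- **Mixture and ranges.** Five classes partition an 80%-forest extent
  with area shares (0.07, 0.02, 0.03, 0.04, 0.84) derived from reported
  class storage/density ratios — shrubs dominate area, trees dominate
  density. Per-class density (mean, min, max) in t/ha: Populus
  (32.31, 4.04, 70.70), Salix (24.01, 2.09, 65.87), Pinus tabuliformis
  (18.25, 8.73, 73.86), other (23.31, 6.53, 45.03), shrub
  (9.13, 3.36, 15.69). The latent field is Gaussian-smoothed white noise
  (σ = 8 px), min-max rescaled per class with a power correction solved
  so the class mean is matched exactly.
- **Reflectance.** Red decreases and NIR increases with the saturating
  response g = d/(d + K), K = 50 t/ha, so NDVI saturates in dense canopy
  — the known failure mode of index-based models. K trades saturation
  realism against the attainable noiseless NDVI–density correlation
  (≈0.97 at K = 50 under the class mixture); stronger saturation would
  cap the generator below its contract of reaching a requested
  correlation within ±0.05. Band noise is a single scale applied to all
  six 10 m bands, solved by bisection so corr(NDVI, density) over forest
  pixels equals the configured `vi_signal_r` (default 0.7, the upper
  range of observed plot-scale correlations). The 30 m bands are exact
  3×3 block means of the clean 10 m bands (green, red, NIR) plus
  independent sensor noise of sd `sensor_noise_sd` (default 0.01
  reflectance units). Non-vegetated land-use classes carry distinct base
  spectra plus a small smooth within-class variation (amplitude 0.008)
  so covariance-based classification is well-posed.
- **Plots.** The survey layout is 20/18/20/18/20 plots per class (96
  total). Stem lists are built by inverting the class's allometric
  model: a stem count is chosen from the plot's carbon, the common
  scalar D²H (trees; taper H = D/2) or the crown volume (shrubs;
  H = 0.8 M) is solved by bracketed root finding, and three herb
  quadrats carry a fixed-mean mass jitter — with zero plot noise the
  accounting round-trips to the local true density to float precision.
  Plot-level noise between inventory and imagery defaults to 10%
  relative (a free parameter; no published value exists).
- **Factor strata.** The maximal-q partition of density with k strata is
  approximated by 1-D k-means; a calibrated number of pixels is then
  randomly reassigned, solved by bisection on the directly computed q,
  so the strata hit a requested between-stratum variance share. A
  request above the k-means partition's maximum is capped with a warning
  — no finite partition of a continuous field reaches q = 1.
- **Determinism.** All draws flow from the root seed through one
  substream per stage (fields/masks 0, density 1, band noise 2, sensor
  noise 3, strata 4, plots 5); identical configs are bit-identical.

What the generator does **not** emulate: atmospheric and topographic
effects, cloud/shadow, sensor PSF and co-registration error, phenology,
within-class species mixtures, and spatially structured (rather than
white) sensor noise. Passing tests therefore demonstrate the correctness
and internal consistency of the algorithms under known ground truth —
not that any given accuracy will be achieved on real imagery.

## Problem sizes and tolerances

The test suite and the acceptance script use 90–300 px square scenes
(0.8–9 k forest ha), 20 scene replicates for the Approach-2 comparison,
50 random vectors for the metric oracle and 10⁴–10⁵ pixels for the
geodetector recovery; these sizes give stable statistics while keeping a
full run in tens of seconds. Oracle agreements are asserted at 1e-12
(metrics), 1e-9 (VIF, noiseless OLS); stochastic recoveries at ±0.05
(geodetector, index-signal calibration) and 3 standard errors (noisy
OLS); conservation at 1e-6 relative.

## Known limitations

- The shipped shrub allometry coefficients are flagged placeholders (see
  above); results for shrub-dominated plots depend on replacing them.
- Approach 2 inherits any bias of the fine-scale models: it converges to
  the *reference*, not to ground truth, and mixed cells below the forest
  fraction threshold are predicted by extrapolation.
- No reprojection: all inputs must share one CRS and, for transfer, an
  exactly nested grid pair.
- The geodetector module implements the factor and interaction
  detectors only (no ecological/risk detectors, no noncentral-F test).
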