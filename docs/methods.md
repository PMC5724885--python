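# Methods

This note records the modelling conventions, default parameters and
design decisions behind `nirscal`, and what the synthetic experiments do
and do not demonstrate.

## Spectra and units

A spectrum is apparent absorbance log₁₀(1/R) on a strictly increasing
nanometre grid.  Reflectance input is converted first; replicate scans
(two cup fillings for mashed samples, proximal/middle/distal positions
for intact roots) are averaged **after** the log transform, since
calibration consumes absorbance — averaging before the transform would
differ only in the third decimal on typical data, but one order had to
be fixed.  Grid trimming (e.g. 350–2500 @ 1 nm → 400–2500 @ 2 nm) is
exact subsampling: every requested wavelength must exist in the source
grid, and no interpolation is ever performed, so trimmed values are a
strict subset of the originals.

## Pre-treatment

Scatter correction and derivatives act independently within three
wavelength segments (350–1000, 1001–1800, 1801–2500 nm by default) and
the treated segments are concatenated back; discontinuities at segment
boundaries are accepted.  Within a segment:

* **SNV** divides the centred spectrum by its own standard deviation.
  The SD uses ddof=1 (sample SD); this is configurable since the
  convention is not universal.  A constant segment is an error.
* **De-trend** subtracts the least-squares quadratic in the 0-based
  within-segment point index k (not raw nanometres); the residual is
  orthogonal to {1, k, k²}.  SNVD applies SNV first, then de-trend.
* **MSC** regresses each spectrum on a reference — the training-set
  mean per segment — and returns (S − b)/a.  The fitted reference is
  stored with the model and reused verbatim when predicting new
  samples; slopes below 1e−8 in magnitude are an error.
* **Norris–Williams derivatives** (code D, G, S1, S2): running-mean
  smooth with window S1, gap difference
  x′ᵢ = x̃ᵢ₊g − x̃ᵢ₋g or x″ᵢ = x̃ᵢ₋g − 2x̃ᵢ + x̃ᵢ₊g,
  then a second smooth with window S2 (placement after differencing was
  an open choice; it is fixed here and configurable only by code).
  Vectors are replicate-padded at the edges before smoothing and
  differencing so every sample keeps the same dimensionality — PLS
  needs a fixed design matrix — at the cost of distorted values within
  G + (S−1)/2 points of each segment edge.

## MPLS calibration

"Modified" PLS is implemented as NIPALS PLS1 on data where the
reference values and every wavelength have been centred and scaled to
SD 1.0.  (Proprietary implementations add further re-weighting passes
whose details are not public; results therefore agree with them only
approximately.)  Conventions:

* SEC = √(SSE/(n − #LV − 1)); SECV = √(mean squared held-out residual)
  with denominator n.  Neither denominator is standardised in the
  field; both are documented here and fixed.
* R²c is the squared correlation of fitted vs observed values.  R²cv is
  the squared correlation of the LOOCV predictions vs observed (the
  1 − PRESS/SST variant is also computed and stored on the model as
  `r2cv_alternative`).
* LOOCV re-estimates the full autoscaling and factor sequence in every
  fold; the number of latent variables is the argmin of SECV over
  1..max_lv (default 16), ties resolved toward fewer factors.
* Scatter corrections are estimated once per calibration round on the
  full retained set, **not** inside each LOOCV fold.  This matches
  common chemometrics practice; the mild optimism it lends SECV (the
  held-out sample contributes to the MSC reference/SNV statistics of
  nothing but itself, so the leak is only through MSC references) is
  accepted and documented.
* H-outliers: squared Mahalanobis distance of a sample's latent scores,
  divided by the number of latent variables (the "global H"
  convention, which makes the customary limit of 10 meaningful);
  t-outliers: |calibration residual|/SECV against a limit of 2.5.  Up
  to 3 rounds of flag → remove → re-select LV → refit are run; a sample
  failing both checks is logged once, as H.  All removals are recorded
  as (iteration, sample id, kind, statistic).
* Zero-variance wavelengths are dropped with a warning; rank exhaustion
  reduces the factor count with a warning; constant references are an
  error.

## Calibration sampling

The calibration/validation split mirrors the *naes* algorithm: PCA on
centred (not autoscaled) absorbance, keeping the smallest number of
components explaining ≥99% of variance; k-means on the scores with k =
desired calibration size, at most 1000 iterations, seeded and
deterministic; the sample nearest each cluster centroid (Euclidean, in
score space, ties to the lowest index) enters the calibration set and
the remainder validate.  Published splits of this kind are not exactly
reproducible without the original random seed — only the set sizes and
summary statistics are.

## Evaluation statistics

bias = mean(ŷ − y); SEP = √(mean((ŷ − y)²)); SEP(C) = √(Σ(ŷ − y −
bias)²/(n − 1)); these denominators imply SEP² = SEP(C)²·(n−1)/n +
bias², which the tests assert.  RPD = SD/SECV in calibration and
SD/SEP(C) in validation; R²p is the squared Pearson correlation.
Published tables round to 2 decimals; the library keeps full precision
and rounds only in presentation columns.

## Reference chemistry

TCC (µg/g) = A·V(mL)·10⁴/(A¹cm·w(g)) with A¹cm = 2592 for β-carotene in
petroleum ether (overridable for other solvents).  Oven DMC =
100·dry/fresh, replicates averaged.  SG = w_air/(w_air − w_water); the
SG→DMC line is a named parameter set: the widely used 158.3·SG − 142,
and a 67.33·SG − 37.03 refit observed on field data.  Note that SG (and
hence SG-derived DMC) *decreases* in w_air at fixed w_water and
increases in w_water — the physically correct monotonicity, which the
tests assert.

## Synthetic data: what it emulates, and what not

The generator draws concentrations from truncated normals with moments
typical of fresh cassava roots (DMC 36.2 ± 4.2% in [20.1, 44.1], TCC
14.9 ± 7.7 µg/g, ATBC 10.1 ± 5.9 µg/g), TCC and ATBC coupled through a
Gaussian copula with correlation 0.9 (one is a component of the other).
Clean absorbance is a fixed fresh-root background (sloping baseline
plus invariant features at 680/970/1450/1940/2270 nm) plus broad
Gaussian constituent bands: carotenoids in the visible (450, 488 nm),
water — modelled as the 100 − DMC complement, since fresh roots are
essentially water plus dry matter — at its 1450/1940 nm overtones, dry
matter near 2100 nm.  Each sample then receives a multiplicative
scatter factor (SD 0.05 around 1), a random quadratic baseline
(coefficient SDs 0.02/0.01/0.005 AU) and iid noise (SD 0.001 AU).
Defaults: n = 150 on 400–2500 @ 2 nm.

Two generator-design points deserve emphasis.  First, the large fixed
background is not decoration: per-segment SNV divides by the segment SD,
and if that SD were dominated by the constituent bands themselves the
normalisation would cancel most of the concentration signal (spectral
"closure").  A strong common structure keeps SNV approximately linear
in the signals, which is also how real spectra behave.  Second, water
as 100 − DMC makes DMC information live in the *contrast* between water
and dry-matter bands, as it does physically.

What the generator does **not** emulate: band-position and band-shape
changes with temperature or matrix, instrument line-shape and
wavelength error, detector-specific heteroscedastic noise, nonlinear
detector response, or inter-constituent chemical interactions.  Passing
the recovery experiments therefore shows the pipeline is implemented
correctly and behaves sensibly under its own model assumptions; it does
not certify performance on any particular instrument or crop season.

`plant_outliers` corrupts copies of a dataset for sensitivity studies:
gross reference errors (±magnitude·SD(y), default 5) that should be
t-flagged, and spectral artifacts (offset + slope + a spurious narrow
band — the band is what survives scatter correction) that should be
H-flagged.

## Problem sizes used in tests and drivers

The default study conditions (150 samples, 1051 wavelengths) are used
where the claim concerns them — the headline recovery check and the
acceptance script.  Everything structural (CV equivalence, outlier
sensitivity across 20 seeds, the pre-treatment grid, split/validation
experiments) runs on a 10–20 nm grid with 60–173 samples: the
properties under test are grid-density-independent, and the coarser
grids keep the full suite to a couple of minutes.

## Known limitations

* MPLS here is autoscaled NIPALS PLS1; vendor MPLS variants differ in
  unpublished details, so printed statistics from such software are
  matched in magnitude, not digit-for-digit.
* SECV carries the documented mild leak through full-set scatter
  correction.
* naes splits depend on the k-means seed; only sizes and summary
  statistics are stable across seeds.
* Edge points of each segment are distorted by replicate-padding in
  smoothing/derivatives.
* The DMC-methods comparison driver (`analysis/04_dmc_methods.py`)
  encodes assumed error magnitudes for the specific-gravity and
  intact-root routes; its correlations characterise those assumptions,
  not any field dataset.
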