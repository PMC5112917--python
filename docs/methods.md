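# Methods

This note documents the statistical models implemented in `moltrace`, the
defaults they ship with, and the design decisions taken where the
underlying field methodology admits more than one reading.

## Data model

Grids (`IsotopeGrid`) are regular, square-celled, north-up arrays in
geographic WGS84, with cell-corner origin and NaN for nodata in memory.
They carry isoscapes (‰), per-pixel SDs (‰), per-bird posterior surfaces
(probability mass per cell) and origin-count stacks. ESRI ASCII round
trips are text-exact; GeoTIFFs store georeferencing in the standard
ModelPixelScale/ModelTiepoint tags with an optional SD band. Point
extraction uses the nearest-cell rule (value of the containing cell) by
default — the reproducible behaviour of GIS raster lookup — with bilinear
interpolation available behind a flag. Distances are great-circle
(haversine, mean Earth radius); at study extents of ~2 000 km the
difference from projected planar distances is immaterial relative to
site-level isotope scatter.

## Calibration (precipitation → feather δ²H)

The rescaling function δ²H_f = a + b·δ²Hₚ is estimated from site-level
summaries (n, feather mean/SD, precipitation mean/SD per site). Each of
`n_boot` (default 1000) replicates draws one simulated feather mean per
site ~ N(f_mean, f_sd/√n) and one precipitation value ~ N(p_mean, p_sd),
fits unweighted OLS of feather on precipitation across sites, and stores
the coefficients. Reported (a, b) are the means of the stored draws and
their SDs the spread; the draws feed the error model downstream.

Choices worth noting:

- **Site-mean draws, not per-bird resampling.** Drawing the site mean with
  its standard error is the minimal faithful reading of simulating data
  "to match site-level means and SDs". A per-bird variant (draw n birds,
  average) is available via `per_bird=True`; with the packaged table the
  two agree to well under one bootstrap SD.
- **One precipitation draw per site per replicate** — the precipitation
  value is a property of the site, not of each bird.
- **Missing SDs** (single-bird sites) are imputed with the mean SD of the
  remaining sites by default; `missing_sd="drop"` excludes those sites.
- **Attenuation is inherent.** Redrawing the predictor with its full
  reported SD every replicate is an errors-in-variables design: the mean
  bootstrap slope is attenuated by roughly var(p) / (var(p) + mean p_sd²)
  relative to the error-free OLS slope. With the packaged table the
  predictor spans ~80 ‰ against ~10 ‰ of per-site precipitation SD, an
  attenuation of ~20 %. This is a property of the published procedure, not
  a defect; parameter-recovery tests therefore use a small-predictor-noise
  configuration when they check the bootstrap against generator truth.

### The calibration-table screen

The packaged 51-site table contains a 16-row block whose precipitation
values (−19 to −26 ‰ at 44–48° N) are grossly inconsistent with the
latitudinal gradient established by every other site at those latitudes
(−70 to −90 ‰), while their feather values are consistent with their
neighbours — the signature of a column transcription error in the printed
source rather than a physical signal. `screen_calibration_sites` fits
p_mean ~ lat + lon by OLS over all sites and flags rows whose absolute
residual exceeds 3.5 robust SDs (1.4826·MAD). On the packaged table this
flags exactly that block and nothing else. Nothing is imputed or altered:
the screen partitions the table and callers (including the acceptance
script) report both fits. On the full printed table the bootstrap yields
(−89.9, 0.16); on the consistent subset (−26.8 ± 6.5, 0.96 ± 0.09), which
covers the published (−37.45, 0.86) within two bootstrap SDs.

### Pooled error surface

Per pixel, pooled² = σ_ind² + (b·SDₚ)² + Var_boot(a + b·δ²Hₚ), i.e.
between-individual variance (default σ_ind = 8.4 ‰, the mean of the
site-level feather SDs), the isoscape prediction error mapped through the
calibration slope, and the calibration-uncertainty variance evaluated from
the stored draws at the pixel's precipitation value. The three error
sources are additive and independent under the model, so they pool in
quadrature; the pooled SD can never fall below σ_ind. With Table-like
inputs (SDₚ in 9–11.3 ‰) the pooled surface spans ≈ 12–15 ‰.

## Kriged δ²H isoscape

Empirical semivariance uses the Matheron estimator per distance bin, with
an optional azimuth/tolerance pair restriction for anisotropy diagnostics.
The stable model is γ(h) = nugget + psill·(1 − exp(−3(h/range)^shape)),
with `range` the *effective* range (γ reaches ~95 % of the sill there) —
conventions differ across geostatistics packages, so this is fixed and
documented; the Gaussian model is shape = 2. Nugget and partial sill are
in ‰². Fitting is weighted least squares with Cressie-style weights
(√pair-count / γ_model), multi-started over range and shape with bounded
parameters. The anisotropic alternative is exposed only as a directional
empirical variogram; a full anisotropic kriging system is out of scope
because no anisotropy parameters are available to anchor defaults.

Ordinary point kriging solves the covariance-form system with a Lagrange
multiplier (weights sum to one) using all sites at every cell — a global
neighbourhood, appropriate for networks of ≤ ~50 sites. Duplicate
locations are averaged first. With a zero nugget the predictor
interpolates exactly; kriging variance is clamped at zero. Competing
surfaces are compared on a holdout by OLS of observed on predicted, with
AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), k = 3, Akaike weights, and the
winning regression's slope and intercept reported with 85 % CIs.

## δ¹³C regression isoscape

Four OLS candidates over {δ²H_f, prop_C4}: each main effect alone, both,
both plus interaction. Candidates are ranked by AICc; within the ΔAICc ≤ 2
confidence set, the least-parameterised model whose non-intercept 85 % CIs
all exclude zero is selected (no model averaging). This simultaneously
implements the "pretending parameter" guard: a variable that enters only
by inflating k fails the CI screen and its model is never chosen over the
nested alternative. If nothing passes, selection returns none and the
caller falls back to intercept-only behaviour. Site-mean residuals of the
chosen model are interpolated by ordinary kriging with a stable variogram
(inverse-distance weighting, power 2, as fallback or on request) and added
to the regression prediction; cells beyond twice the maximum pairwise site
distance have no data support and carry a zero residual correction.

## Assignment to origin

The posterior is the normal density of the observed δ²H_f at each finite
cell (mean = isoscape, SD = pooled surface), normalised to sum to one over
finite cells — a flat spatial prior over the isoscape's support, with no
range-map clipping. The likely-origin region is the smallest top-mass set
of cells reaching odds/(odds+1); mass-ties at the cut are taken in fixed
row-major order, keeping the region minimal and deterministic (the
alternative of absorbing all tied cells can only arise with exactly equal
floating-point masses, where it would break minimality — e.g. a uniform
posterior would return the entire grid). Residents are birds whose
collection cell lies in their region; remaining birds are north migrants
when observed < predicted at the collection cell and south otherwise, with
the measure-zero exact tie deterministically labelled south and flagged.
Under a correctly specified error model, birds sampled at their molt
origin are classified resident at the nominal odds mass (≈ ⅔ at 2:1),
which is the property the validation accuracy measures.

## Diet mixing

%C4 = 100·(δ¹³C − C3end)/(C4end − C3end), with endpoints calibrated per
population as the 5th/95th percentiles of that population's feather δ¹³C
(linear interpolation between order statistics; other quantile rules are
switchable). The percentile span is checked against the expected ~15 ‰
feather-space separation of pure C3 (≈ −27 ‰) and pure C4 (≈ −12 ‰) diets;
"conforms" is operationalised as |span − 15| ≤ 3 ‰, and nonconforming
populations still compute with a warning. Birds outside the endpoints are
clamped to 0 %/100 % and flagged. The ~1 ‰ diet-to-feather discrimination
is absorbed by the empirical endpoints; no explicit correction is applied.

## Group statistics

- **LDA classification**: pooled covariance, equal priors, resubstitution
  rates (the defaults of the classical SAS procedure this table format
  comes from, and the only reading consistent with one printed percentage
  per combination); leave-one-out rates behind a flag. Printed-table
  analogs round to integer percent.
- **Stepwise selection**: forward entry by the largest Wilks' Λ partial F
  with entry/stay significance 0.15 (the procedure's default), backward
  removal check each round; the final set is summarised by Λ and Rao's F
  approximation.
- **perMANOVA**: Anderson's partitioning of pairwise squared Euclidean
  distances, pseudo-F = (SS_B/df_B)/(SS_W/df_W), unrestricted permutation
  of raw rows; p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1). When the data
  admit fewer distinct label arrangements than requested permutations the
  exact enumeration is used. For univariate responses the pseudo-F reduces
  algebraically to the one-way ANOVA F (verified against an independent
  implementation in the tests).
- **CI letters**: states ordered by mean; every maximal run of states
  whose 95 % CIs pairwise overlap shares a letter.

## Synthetic study system

`SimulationConfig` defaults emulate the real study's magnitudes: the
precipitation surface is a plane spanning ≈ −20 ‰ (SE corner) to −101 ‰
(NW corner) over 29.5–48.6° N × 109.1–89.6° W plus a smooth random field
(white noise convolved with an exp(−3d/range) kernel, SD 3 ‰, range
300 km — an approximation to an exponential-covariance field; only
smoothness and a controllable correlation length matter downstream), with
a per-pixel SD band uniform on 8.9–11.3 ‰. Feather δ²H follows
−37.45 + 0.86·δ²Hₚ with σ_ind = 8.4 ‰ of between-individual scatter;
δ¹³C mixes −27/−12 ‰ endpoints with per-bird Beta(2, 2) C4 fractions and
1 ‰ residual noise; δ¹⁵N is N(10, 1.7) ‰ with an optional +2 ‰ arid-site
shift (off by default). Sites are placed uniformly with ≥ 5 km spacing by
dart-throwing with bounded retries. All generators are deterministic under
the config seed via independent substreams.

What the generator does *not* emulate: the real precipitation isoscape's
fine spatial texture, molt-dispersal movement between breeding and molt
sites, coupling of individual diet to local crop cover, coastal/brackish
foodweb enrichment, and irrigation-driven δ²H anomalies. Tests passing on
synthetic data therefore demonstrate the correctness of the machinery and
its statistical calibration, not field-level predictive accuracy.

## Problem sizes and numerics

Default test problem sizes (30–40 sites, 8–10 birds/site, 40×48 to
100×120 grids, 200–1000 bootstrap replicates or permutations) were chosen
so each property is measured with adequate Monte-Carlo resolution while a
full run stays interactive. Variogram fits are multi-start bounded WLS;
kriging variances and pooled variances are clamped at zero; posterior
densities are computed in log space and shifted before exponentiation.
Degenerate inputs (constant fields, duplicate sites, all-nodata grids,
saturated regressions, < 3 calibration sites) raise informative errors or
are averaged/flagged as documented above.

## Known limitations

- Single-azimuth anisotropic kriging is not implemented (diagnostic
  directional variograms only).
- Assignment uses δ²H alone; no multi-isotope joint likelihood or
  abundance-informed prior.
- No reprojection: all grids must already be geographic WGS84 north-up.
- The δ¹³C isoscape inherits the weak explanatory power of its covariates;
  it is retained for completeness, with validation tooling to quantify it.
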