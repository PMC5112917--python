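# moltrace

Multi-isotope tracing of molt origin for migratory birds associated with
agro-ecosystems.

Feathers are metabolically inert once grown, so their stable isotope ratios
record the place and foodweb where they were formed. `moltrace` implements a
complete analysis pipeline for the classic three-isotope design used for
Red-winged Blackbirds sampled near sunflower and rice production:

- **δ²H → geography.** Growing-season precipitation δ²H (δ²Hₚ) follows a
  strong continental gradient. A bootstrap regression across known-origin
  calibration sites rescales a precipitation isoscape into feather space
  (δ²H_f = a + b·δ²Hₚ), propagating between-individual variance, per-pixel
  isoscape prediction error, and calibration uncertainty into a pooled
  per-pixel SD.
- **Likelihood assignment to origin.** Each bird's observed δ²H_f is compared
  to the feather isoscape cell by cell through a normal density
  f(y\*|μ_c, σ_c); normalising gives a posterior origin surface. The smallest
  set of cells holding odds/(odds+1) of the mass (2:1 odds → top ⅔) is the
  bird's "likely origin"; birds whose collection cell falls inside it are
  residents, the rest are north/south migrants by the sign of
  observed − predicted.
- **Kriged spring isoscapes.** Site-mean δ²H_f can also be interpolated
  directly by ordinary kriging (Matheron variograms, stable/Gaussian models,
  WLS fitting, leave-one-out RMSE), with competing surfaces compared on a
  holdout by AICc of observed ~ predicted.
- **δ¹³C → diet and a regression isoscape.** Feather δ¹³C mixes C3
  (≈ −27 ‰) and C4 (≈ −12 ‰) dietary endpoints. A two-source linear mixing
  model with percentile-calibrated endpoints (5th/95th) estimates each
  bird's %C4; a four-candidate regression (δ²H_f, county C4 crop proportion,
  additive, interaction) with AICc ranking and an 85 % CI screen builds a
  δ¹³C surface with kriged residual correction.
- **Group statistics.** Linear discriminant classification of collection
  state from isotope combinations, forward stepwise selection with Wilks' Λ
  partial-F tests, permutational MANOVA (Anderson's pseudo-F on Euclidean
  distances) for resident/migrant contrasts, 95 % CI letter groupings and
  isotope-geography correlations.

A `synthetic_data` module generates a full artificial study system —
precipitation surface with SD band, spaced collection sites, per-bird
feather values from the calibration model, crop covariates — so every stage
is testable without external rasters or downloads.

## Worked example

```python
import moltrace as mt

# 1. calibrate the rescaling function from the packaged 51-site table,
#    screening out the internally inconsistent block of printed rows
sites = mt.load_calibration_sites()
consistent, flagged = mt.screen_calibration_sites(sites)   # 35 kept, 16 flagged
rf = mt.fit_rescaling_bootstrap(consistent, n_boot=1000, seed=1)
# d2H_f = -26.79 (SD 6.55) + 0.962 (SD 0.090) * d2H_p   [1000 replicates]

# 2. a synthetic study system over the real extent (29.5-48.6N, 109.1-89.6W)
sim = mt.SimulationConfig(seed=7)
precip, precip_sd = mt.make_precip_isoscape(sim)   # ~ -20 permil (SE) to -101 (NW)
birds = mt.simulate_feathers(sim, mt.sample_sites(sim, 30), 8, precip)

# 3. feather isoscape + pooled per-pixel error, then assignment
feather = mt.apply_rescaling(precip, rf)
pooled = mt.pooled_error_surface(mt.ErrorModel(8.4, precip, precip_sd), rf)
# pooled SD range: 12.1-14.5 permil
oa = mt.assign_bird(birds[0], feather, pooled)
# bird S001-B001: status 'north', observed -95.6 vs predicted -76.2 permil,
# likely-origin region 4314 of 12000 cells
mt.validate_assignment(birds[:100], feather, pooled)
# 0.65 of birds sampled at their origin fall inside their own 2:1 region
# (nominal coverage is 2/3)

# 4. diet: percent C4 per population from percentile endpoints
mt.population_summary(birds)
#  state  pct_c4_mean  pct_c4_sd    n     p5    p95
#    SIM        52.0       30.7   240  -25.1  -14.0
```

The same workflow is scriptable from the shell: `moltrace simulate`,
`moltrace calibrate`, `moltrace rescale`, `moltrace assign`, `moltrace mix`,
`moltrace classify`, `moltrace permanova` (see `moltrace --help`).

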