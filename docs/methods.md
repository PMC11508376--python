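# Methods

## The connectivity measure

Each sampling site *i* is scored against a fire-history register by

    ST_i = Σ_j  exp(−d_ij · α_s) · FA_j · exp(−T_j · α_t),

summing over all register fires *j* within a truncation radius of the site.
This is a patch-connectivity measure of the incidence-function family,
extended with a temporal decay: a fire contributes its log burned area,
discounted exponentially in distance and in time since it burned. The terms
are:

* `d_ij` — planar Euclidean distance in km, centre of the fire to the site.
  Coordinates must be in a projected metric CRS; no geodesy is done. The
  register records a total area but no perimeter, so a circular extent around
  the recorded centre is the only available geometry; by default distances are
  centre-to-centre, and an optional `edge_distance` mode subtracts the circle
  radius √(area/π) (floored at 0) for users who prefer edge distances to
  large burns.
* `FA_j = ln(area_j)` with area in m². The log base is a convention: base-10
  rescales every term by 1/ln 10, which the standardized slope absorbs and
  the scale optimization is indifferent to (the rescaling is uniform across
  sites). Natural log is the default, matching the incidence-function
  literature; `log_base="10"` is available and recorded in output headers.
* `T_j = sampling_year − fire_year`, whole years, ≥ 1 (fires must be strictly
  prior to sampling; the register has no within-year timing).
* Truncation radius: 20 km, boundary inclusive. The measure is continuous in
  distance so the boundary convention is numerically immaterial; inclusivity
  is fixed for reproducibility.

Fires below 1 m² would contribute negative log-area weights and are rejected;
with the default register cut-off of 100 m² (inclusive — registers round, so
exactly-at-threshold records are common and kept) the situation cannot arise.
Areas in [1 m², e m²) give weights in [0, 1) and are permitted only in
non-default configurations.

## Response and model

The response is the per-site natural-log odds that a randomly drawn caught
individual (or species) belongs to a focal group: `ln(k/(n−k))`. Groups
(pyrophilic / non-pyrophilic / obligate saproxylic) overlap, so each group ×
level combination is an independent analysis on the same sites. Species-level
odds use raw per-site species counts, not abundance-weighted incidence. A
zero cell (k = 0 or k = n) gets a Haldane continuity constant c = 0.5 added
to both cells; c is configurable, the correction is applied only when a cell
is zero, and every adjusted site is flagged in the output. Sites with n = 0
carry no information and are dropped with a log message.

The regression is a normal-family GLM with identity link — ordinary least
squares, fitted via statsmodels — of ln-odds on connectivity standardized to
sample mean 0, sd 1 (ddof = 1). Deviance is therefore the residual sum of
squares exactly, not approximately. p-values are two-sided t-tests with n − 2
degrees of freedom, reported raw with no multiple-testing adjustment.

## Scale optimization

(α_s, α_t) are chosen by grid search over [0, 4] × [0, 4] (default step 0.1,
1681 refits): at each grid point connectivity is recomputed, re-standardized
(the predictor changes with the scales, so standardization must be inside
the loop for slopes to stay comparable), and the model refit; the minimizing
pair wins. Grid search rather than a continuous optimizer because the
deviance surface can be multi-modal and the grid is cheap. Exact ties break
to the lexicographically smallest (α_s, α_t) — the smoothest kernel — for
reproducibility. Each response profiles its own scales. A grid point with
constant connectivity (e.g. no contributing fires) is degenerate and scored
with the intercept-only deviance; a profile that is degenerate everywhere is
an error, and in the six-way report a degenerate combination is reported as
such without aborting the others.

The inner loop is a closed-form vectorized RSS (the temporal kernel
factorizes as exp(−α_t T_ij) = exp(−α_t(s_i − y₀))·exp(−α_t(y₀ − y_j)), so a
whole α_t row costs one mat-vec); it is tested against the naive
per-point pipeline (double-loop connectivity → standardize → statsmodels
OLS).

**Selection inference caveat.** Optimizing the scales and then reading the
slope's p-value at the optimum is anti-conservative: under a true null the
search picks the scales that make the slope look best. The package reports
the raw p-value, flags the issue, and demonstrates it empirically (null
simulations show size ≈ 0.3–0.4 at nominal 0.05 with optimization on, vs
≈ 0.05 at fixed scales). Correcting for the search is out of scope.

## Synthetic data generator

The generator emulates a 12-year county fire register and a smoke-trap
survey; its defaults are the study-scale conditions:

* fires: per-year count ~ Poisson(118) over 12 years (≈ 1416 fires on a
  100 km square, matching the register's ≈ 1419 and its per-area density of
  ≈ 0.0054 fires km⁻² yr⁻¹); areas lognormal on the log-m² scale
  (μ = 8, σ = 1.8, chosen so the mean area ≈ 1.4 × 10⁴ m² reproduces the
  register's ≈ 20.5 km² total over ≈ 1400 fires), truncated at the 100 m²
  cut-off by inverse-CDF sampling; locations uniform, or a Thomas-style
  parent/offspring cluster process (`cluster_sd_km` > 0) since real
  registers are spatially clustered;
* sites: uniform with rejection to enforce ≥ 7 km pairwise separation
  (default 21 sites), sampled the year after the register closes;
* catches: per site, total individuals ~ Poisson(106) (the survey's 2220/21)
  and species ~ Poisson(40, a plausible per-site richness chosen once);
  focal counts are Binomial(total, p_i) with
  logit p_i = baseline + β·z_i, z_i the standardized true-scale
  connectivity, baseline −3.58 for individuals (2.7% pyrophilic at the mean)
  and −2.48 for species; control-group counts are drawn with no connectivity
  effect, at rates matching the survey's composition. Generating from the
  binomial-logit model and analysing with the ln-odds normal GLM is
  deliberate: it tests the method as used, not an idealized version of it.

What the generator does not emulate: forest-cover heterogeneity, fire
spread/shape, within-year timing, wind or smoke-plume geometry,
between-site differences in trapping conditions, and species-level
correlation between the individual and species responses. Passing recovery
tests therefore show the estimator works when its structural assumptions
hold at realistic rates and sample sizes — not that real surveys are free of
the confounders above.

**Known attenuation.** At study-scale catch sizes (~106 individuals/site,
mean pyrophilic count ≈ 3 at baseline) the empirical ln-odds is a noisy,
censored transform of the true logit (zero cells are frequent and the
continuity correction bounds them), so the fitted slope at the true scales
underestimates the generative β by ≈ 12% at β = 2. The effect vanishes as
catch totals grow (bias ≈ 0 at 20 000 individuals/site) — it is a property
of empirical-logit analysis of small counts, not of the implementation, and
the corresponding recovery test asserts the unbiasedness that an exact
method would show and fails honestly at survey-scale counts.

## Validation problem sizes

Scale recovery uses 200 sites on a 300 km square (fire rate 485/yr preserves
the register's per-area density on the larger landscape needed to hold 200
sites ≥ 7 km apart), β = 2, grid step 0.2, 200 replicates: the profiled
scales land within ±0.5 of the truth in ~100% of replicates. Null
calibration uses 100 sites on a 150 km square (fire rate 121/yr, same
density), β = 0: 1000 replicates at fixed scales (empirical size ≈ 0.056)
and 300 with optimization on (≈ 0.38). Replicate r reseeds the generator
with seed + r.

## Limitations

* No spatial autocorrelation correction (site separation is the design-based
  defence); no mixed models; no information-criterion comparison.
* No rarefaction or effort correction across sites — effort is assumed
  standardized in the field.
* The descriptive register metadata shipped with the package includes a
  printed forested-area percentage that is inconsistent with the printed
  areas it derives from; both are carried as metadata only and never used in
  computation.
* Study-data replication requires the archived site-level deposit, which is
  not redistributed here; `tests/test_acceptance.py::test_study_data_replication`
  documents the expected values and fails until the deposit is placed under
  `data/study/`.
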