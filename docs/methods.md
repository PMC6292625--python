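# Methods

This note documents the models, numerical choices and limitations of
`famap`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The food-availability indicator

FA = (E_consumed + E_income) / (365 · n_hh-mae), in kcal per male adult
equivalent per day.

* **E_consumed** sums (produced − sold) × energy density over all crop
  and livestock products. Sold quantities exceeding production are
  clipped to production with a warning (survey noise); a strict mode
  raises instead. Products missing from the energy table fail loudly —
  a silent zero would bias FA downward.
* **E_income** converts all cash income (product sales at farm-gate
  prices plus off-farm income) into the energy of the staple food
  (maize by default) it could purchase at the configured staple price.
  The staple price is a configurable scalar; no price series is
  modelled.
* **n_hh-mae** sums sex- and age-band weights relative to an adult
  male (2500 kcal d⁻¹, weight 1). The shipped weight table
  (`famap/data/mae_weights.yaml`) is an editable default in the style
  of published adult-equivalent scales, not a copy of a specific
  source; correctness of the MAE standardisation is defined relative
  to the configured table. The same holds for the energy-density table
  (`famap/data/energy_table.csv`): the values are plausible
  placeholders for the product groups the pipeline consumes.
* **Contribution shares** attribute each product's consumed energy and
  its sales income (in staple-energy terms) to the product's own
  group; off-farm income goes to the off-farm activity. This is the
  one attribution under which activity shares, crop-group shares and
  livestock-group shares are simultaneously energy-consistent and
  nest exactly. Income from livestock services (draught, manure) is
  not captured. With zero total energy the share vector is undefined
  and returned as flagged zeros.
* **Inclusion filter**: households with land holdings and at least one
  livelihood activity (any production, or off-farm income) are
  retained; exclusions are logged with reasons.

## Zero-and-one-inflated beta regression

Shares are modelled with the four-parameter mixed distribution
(μ, σ, ν, τ): Beta(α, β) on (0,1) with α = μ(1−σ²)/σ²,
β = (1−μ)(1−σ²)/σ², endpoint masses P0 = ν/(1+ν+τ),
P1 = τ/(1+ν+τ), and E(y) = (τ+μ)/(1+ν+τ).

* **Links**: logit for μ and σ (both live in (0,1)), log for ν and τ —
  the conventional parameterisation for this distribution family.
* **Fitting**: joint maximum likelihood over all coefficient vectors,
  quasi-Newton (BFGS) with numerical gradients, started from
  moment-based intercepts (logit of the interior mean, dispersion from
  the interior variance, log odds of the empirical endpoint
  frequencies) and zero slopes, with a Nelder–Mead polishing pass if
  the line search stalls. Standard errors come from the inverse
  observed information (numerical Hessian); AIC = −2ℓ + 2k.
  Non-convergence is flagged on the returned model, never silent.
  Linear predictors are clipped at ±30 on the link scale to keep the
  likelihood finite in extreme regions of the parameter space.
* **Family choice**: samples with ≤ 3 exact ones are considered too
  small to model the y = 1 mass and use the zero-inflated-only variant
  (no τ). Any such exact ones carry zero probability under that model
  and are excluded from the fit with a warning/log entry — the
  operational reading of "too few to predict".
* **Covariate selection**: (1) univariate screening keeps covariates
  whose slope is significant at p < 0.1; for the inflated-beta
  families the slope is tested on the μ predictor by default
  (configurable to any-parameter, taking the smallest p). No
  multiple-testing correction is applied at this raw screening gate.
  (2) Iterative VIF filtering drops the highest-VIF covariate until
  all VIF < 10. (3) Stepwise AIC selection: forward for the linear
  model; for the inflated-beta families a cycle over μ → σ → ν → τ of
  forward additions then backward eliminations, repeated to a fixed
  point. Candidate fits that fail are skipped and logged.
* **Simplification**: after selection, the last-added coefficient of
  each distribution parameter is a removal candidate. The source
  wording of this rule is ambiguous in two places (whether candidates
  are the significant or the non-significant terms, and the direction
  of the AIC-difference guard). The default `corrected` rule removes a
  *non-significant* (p ≥ 0.1) last coefficient and accepts the
  simplification unless it worsens AIC by more than 10 — the reading
  under which the step reduces overfitting. The `literal` rule applies
  the wording verbatim and is available by configuration.
* **Fit statistic**: pseudo-R² — the squared Pearson correlation of
  fitted E(y) and observed y; returned as 0 with a warning when either
  vector is constant (e.g. an intercept-only negative control).
* **Nested EVHR fit**: household-resource covariates (cultivated land,
  herd size TLU, household size) are added to the selected
  environmental model by forward AIC steps only, keeping all
  environmental terms, so the EVHR model nests the EV model.

FA itself is fitted as OLS on log-FA (non-positive FA values are
dropped before the log with a log entry); standardised coefficients
(coef × sd(x)/sd(y)) are reported alongside.

## Residual geostatistics

* **Normal scores**: residuals are mapped through a 100-interval
  quantile table spanning the 0.5 %–99.5 % probability range, with
  piecewise-linear interpolation in both directions. Values beyond the
  truncation quantiles map to the boundary scores, and scores beyond
  the bounds invert to the boundary data values. Ties share a score;
  constant input is an error. Truncation trades tail fidelity for
  robustness of the large-scale pattern.
* **Empirical variogram**: method of moments over all point pairs
  within a 200 km cutoff, with default lag boundaries at
  10…100, 150, 200 km. Distances are great-circle kilometres on WGS84
  (the analysis stays in geographic coordinates; no projection).
  Coincident pairs (distance 0) fall in no positive-lag bin.
* **Model fitting**: spherical and Matérn κ = 0.5 (exponential)
  candidates, fitted by least squares weighted with pair count over
  squared mean lag distance, from a grid of starting values; the shape
  with the smallest weighted SSE wins. The nugget is bounded below by
  0 and the range is bounded above by 1.5 × the largest observed mean
  lag — structure beyond the sampled lags is not identifiable, and an
  unbounded range admits degenerate quasi-linear fits. The reported
  sill is the **total** sill (nugget + partial sill); the nugget-sill
  ratio divides by it, which is the convention consistent with the
  published table this arithmetic is checked against. The ratio-≤-0.7
  rule classifies indicators as spatially structured.
* **Kriging**: ordinary kriging by default (locally re-estimated
  mean); simple kriging with known mean 0 is available and suits
  normal-score residuals. The covariance at distance zero includes the
  nugget, so kriging honours the data exactly. Systems are solved
  globally below 2000 points and with the 64 nearest neighbours above
  (configurable); a singular system is retried with a jittered
  diagonal. For FA, regression kriging combines the OLS trend with
  kriged OLS residuals; the trend is treated as deterministic and the
  prediction standard deviation is the residual kriging standard
  deviation.
* **Cross-validation**: leave-one-out diagnostics (mean error, RMSE,
  mean standardised squared error) computed with the closed-form
  precision-matrix identities, so one factorisation serves all points;
  the identity is verified against direct re-kriging in the tests.
  MSSE near 1 indicates calibrated kriging variances.

## Map composition

Proportion maps: the kriged residual mean and μ ± 1.96 σ bounds are
back-transformed through the inverse normal score map (the transformed
mean becomes the back-transformed *median*) and added to the
regression surface, which is treated as deterministic — all mapped
uncertainty is residual uncertainty. Sums are clamped to [0, 1]
*after* addition. FA maps: E(Y) = e^μ is the lognormal median (not the
mean), with bounds e^(μ±1.96σ); values are non-negative by
construction. Cell-wise ordering lower ≤ median ≤ upper is enforced
and checked.

## Synthetic scenes

The generator emulates the structure of a clustered, privacy-displaced
agricultural survey at country scale:

* **Covariates**: independent Gaussian random fields with configured
  marginal mean/sd and exponential correlation (the `range_km`
  parameter is the exponential distance parameter). Fields are
  simulated exactly by Cholesky factorisation below 5000 grid cells
  and by FFT circulant embedding above (negative embedding eigenvalues
  clipped — an approximation that is irrelevant below the cutoff).
* **Locations**: enumeration-area centroids uniform in the extent,
  households Gaussian-scattered around them (rejection-resampled into
  the extent), then displaced ≤ 10 km at uniform bearing for
  publication. Generating fields are evaluated at the *true*
  locations; analysis sees the displaced ones, reproducing the
  spatial-mismatch noise of real published surveys.
* **Indicators**: each share indicator draws from the inflated-beta
  mixture with link-scale linear predictors of the standardised
  covariates plus a single shared latent residual field (drawn from
  the truth variogram) entering each parameter's predictor with a
  per-parameter scale. The source workflow has no generative model;
  this shared-field construction is the simplest structure that yields
  spatially structured residuals of E(y) and is a stand-in, not an
  estimate of any real process.
* **Composition constraint**: indicators are simulated independently,
  so household share vectors exceeding total 1 are rescaled into the
  simplex and the shortfall is assigned to a residual crop group. For
  typical configurations the rescaling touches few households, so the
  marginal inflated-beta structure is essentially preserved.
* **Survey inversion**: rosters, production, sales and income are
  constructed so that recomputing FA and shares from the records
  reproduces the targets exactly: each on-farm group's target energy
  becomes production of a representative product, part of which is
  sold at the *energy-neutral price* (product energy per currency
  equal to the staple's), which exercises the sales pathway without
  changing FA or any share; off-farm energy becomes income via the
  staple conversion.
* **Default conditions** mirror the study scale: a ~5.5° × 5.5° extent
  on a 5-arc-minute grid, 160 enumeration areas × 12 households
  (≈ 1.9 k households), 2 km cluster scatter, 10 km displacement,
  50 m de-duplication jitter, nine covariate layers. The default
  indicator truths were chosen, once, by forward simulation so that
  the generated scene reproduces the qualitative contrast the
  procedure is meant to diagnose: a "banana-like" indicator driven by
  environmental gradients with strongly structured residuals
  (fitted pseudo-R² and nugget-sill ratio in the neighbourhood of the
  published banana column), a "beans-like" pure-noise indicator (no
  covariate effect, pure-nugget residual), weakly structured off-farm
  and cattle indicators, and an FA model with a large-nugget residual
  variogram.
* **Determinism**: one scene seed; stage sub-seeds derived by fixed
  offsets. Identical (config, seed) pairs give bit-identical scenes.

**What passing tests do and do not show.** The generator produces
exactly inflated-beta data with linear link-scale effects and a
Gaussian shared residual — the model family the pipeline fits. Passing
recovery tests therefore demonstrates correctness of the machinery,
not robustness to the misspecification, measurement error and
non-linear effects of real surveys. Two real-data features *are*
emulated (location displacement and enumeration-area clustering); many
are not (reporting error, price heterogeneity, informative sampling,
covariate measurement scales). Because both the covariate fields and
the latent residual are smooth fields over a single country-sized
domain, their chance correlation in any one realization can noticeably
raise or lower the realized pseudo-R² — the same single-realization
variability a real survey year embodies — so end-to-end statistics
vary across scene seeds even at fixed truth.

## Soil carbon stock

SCARB_i = BD_i × Δz_i × SOC_i × 10⁴ per depth layer (0–5, 5–15,
15–30 cm), averaged over the three layers. The formula is implemented
literally. Note the unit printed for SCARB in the source material
(kg C Mg⁻¹, the SOC unit) is not dimensionally consistent with the
product, which — with BD in Mg m⁻³, Δz in m and the 10⁴ m² ha⁻¹
factor — yields a mass of carbon per hectare per layer. The
implementation reproduces the arithmetic and leaves the unit question
open.

## Numerical and engineering choices

* Distances: spherical earth, WGS84 mean radius 6371.0088 km;
  adequate at 10 km grid resolution.
* Grid cells are half-open ([x, x+dx) × (y−dy, y]), so edge points
  belong to exactly one cell and raster sampling is deterministic.
  Resampling aggregates source-cell centres by mean; nodata propagates.
* De-duplication jitter: ≤ 50 m uniform-bearing offsets, re-drawn on
  residual collision (bounded retries), as kriging requires unique
  locations.
* Rasters are stored as ESRI ASCII grids — a plain-text, widely
  readable raster format; a stack is a directory of `.asc` files.
* The pipeline isolates per-indicator failures (a non-converging model
  yields a failure row, never an aborted run), logs stage boundaries
  with record counts, and stamps every report with the package version
  and a config hash.

## Known limitations

* The inflated-beta optimiser uses numerical derivatives; fits with
  many covariates on all four parameters are slower than an
  analytic-gradient implementation would be.
* Variograms are isotropic; no anisotropy, co-kriging or Bayesian
  uncertainty in the variogram parameters.
* Regression-parameter uncertainty is deliberately not propagated into
  the prediction intervals (the regression surface is treated as
  deterministic), so the intervals understate total uncertainty where
  the trend model itself is poorly determined.
* The FA prediction interval uses the residual kriging standard
  deviation on the log scale; back-transformed intervals are
  asymmetric and refer to the median.
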