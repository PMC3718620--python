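# Methods

This note documents the statistical model, the synthetic study conditions,
the numerical machinery, and the design decisions behind `countyprev`. It is
written for someone who wants to judge what the package's passing tests do
and do not demonstrate.

## Outcomes

Three binary outcomes per respondent:

* **obesity** — corrected BMI ≥ 30 kg/m² (inclusive). BMI is
  weight (kg) / height² (m²) from self report, corrected as described below.
* **any physical activity** — the direct yes/no leisure-activity response.
* **sufficient physical activity** — moderate-equivalent weekly minutes
  (moderate + 2 × vigorous) ≥ 150. Both the 150-minute threshold and the
  vigorous multiplier of 2 are configuration values (defaults follow the
  2011 guideline definition, applied uniformly to all survey years); changing
  the threshold is the single lever for guideline sensitivity analyses. A
  frequency × duration input form is converted to weekly minutes before
  classification.

Records missing age, sex, race or county are excluded from all models;
records missing one outcome are excluded from that outcome's model only.
"Don't know/refused"-style responses are represented as missing — the
package recognises no numeric sentinel codes.

## Self-report calibration

For every two-year examination cycle, mean BMI by sex × age group is computed
from the self-report records (reported) and from examination data (measured).
Matched cells are pooled across cycles into one OLS per sex of measured on
reported; corrected BMI is the fitted linear map applied to each individual.
Pooling across cycles (rather than one fit per cycle) is the package's
reading of the calibration design: a single time-constant per-sex map, which
is also the assumption stated for the original correction (misreporting not
varying over time or place). Cells are unweighted by default; weighting by
cell count is available behind a flag. Corrected BMI is never truncated; an
optional range filter exists but is off by default.

The calibration is exactly invertible only when the reporting distortion is
affine on the BMI scale and cells are noise-free; the generator is built so
this regime exists (below), and the round-trip test exercises it.

## Model

For outcome, sex and window (five consecutive years), with respondent *i* in
county *c*:

logit P(y=1) = β₀ + Race'βR + Age'βA + δ·(t − t̄) + x_c(t)'γ + θ·g_c + u_c,
u_c ~ N(0, σ²ᵤ) i.i.d.

* Race reference is white, age reference 20–34; t̄ is the window midpoint
  (pure reparameterization to decorrelate intercept and slope; predictions
  are unchanged).
* County covariates x_c(t): poverty, unemployment, percent rural, percent
  with a high-school diploma, PM2.5 — plus doctors/dentists per 100k for
  obesity only. Covariate and full variants also include county racial
  composition (shares of the four non-reference groups), so both individual
  race effects and contextual composition effects are represented.
* g_c is the geospatial term: the arithmetic mean of the neighboring
  counties' empirical-Bayes posterior random-effect means from a first-stage
  fit (naive stage for the geospatial variant, covariate stage for the full
  variant). It is computed exactly once — no iteration to a fixed point —
  and enters the second stage as an ordinary fixed covariate. An isolated
  county, or a neighbor absent from the first stage, contributes 0 (the
  prior mean).
* Models are fit separately by sex. Survey weights are not used inside the
  models; representativeness is recovered downstream by race/age
  poststratification. Windows slide one year at a time; annual estimates are
  the unweighted mean over all windows covering the year (computed draw-wise,
  so interval endpoints inherit the window averaging).
* Sufficient-activity models consume only the years where the detailed
  minutes exist inside each window (odd years under the default design); the
  time trend remains linear in calendar year.

### Fitting

Observations are aggregated to binomial cells (county × year × age × race),
which makes the likelihood cheap at survey scale. For fixed σ², (β, u) are
maximised by penalized Newton iteration with step halving; σ is then
profiled by a bounded scalar search (log σ ∈ [log 10⁻³, log 5], tolerance
10⁻⁴) on the Laplace-approximate marginal log likelihood

ℓ(σ) = ℓ_data(β̂, û) − û'û/2σ² − (C/2)·log σ² − ½ Σ_c log(w_c + 1/σ²),

where w_c is county *c*'s accumulated Fisher weight. When the profile
maximum is at the lower boundary (including whenever there is a single
county) the model collapses to ordinary logistic maximum likelihood, which
is returned exactly — this is the oracle identity the tests check against
statsmodels' GLM at 10⁻⁶. On multi-county data the fitter agrees with
`lme4::glmer` (Laplace, nAGQ=1) to ~0.01 on fixed effects and ~10⁻⁴ on σ²
in the cross-check test; the residual difference is the known gap between
profiling β through the penalized objective versus lme4's PIRLS.

Inner Newton convergence: gradient sup-norm or relative objective change
below 10⁻¹⁰ (10⁻¹² for the final polish), cap 100 iterations; a 10⁻¹⁰ ridge
stabilises the Hessian solve. Rank-deficient designs raise a collinearity
error naming the dependent columns via pivoted QR. An identically-zero
column (the degenerate geospatial term produced by an all-zero first stage)
is fit without and reported with coefficient exactly 0, so the degenerate
second stage reproduces the first. Separation is diagnosed when the
unpenalized fit fails to converge with a diverging linear predictor
(|η| > 30).

Posterior county means û_c and variances come from the penalized fit at σ̂;
the joint covariance over (β, u) is the inverse penalized Hessian —
the Gaussian approximation consumed by the uncertainty simulation. Counties
contributing no data receive û_c = 0 with variance σ̂²ᵤ (the prior),
inflating their interval width accordingly.

## Aggregation and uncertainty

All-race estimates are population-weighted averages of race-specific
predictions using county race populations pooled over the study period (one
weight set per county). Age standardization uses an injected standard
population; the shipped asset is the 2000 US census adult age structure
(weights ≈ 0.293, 0.225, 0.188, 0.121, 0.092, 0.083 for the six groups).
Both operators are convex combinations, so estimates stay inside the convex
hull of the cell predictions.

Uncertainty is simulated: n_draws (default 1000) joint Gaussian draws of
(β, u) from the fit's covariance, each pushed through predict → race
aggregation → age standardization; intervals are 2.5/97.5 percentile
intervals (percentile, not normal-theory, matching the asymmetric intervals
such data produce). The same draw index means the same parameter draw in
every county and year, and window averaging happens per draw, so 2001→2009
differences carry the right correlation. A covariance that fails positive
semidefiniteness is repaired by eigenvalue flooring with a logged warning
(or raises, if repair is disabled). The exact simulation scheme is this
package's documented choice; the reporting convention it implements
(simulation-based percentile intervals) is standard for this family of
methods.

## Validation experiment

Gold counties: ≥ 900 usable records pooled over 2001–2005 (inclusive
boundary). The gold standard is the direct pooled proportion. For each
m ∈ {10, 50, 100} and replicate (default 25 — the source design says only
"repeatedly"), gold counties' records are replaced by an m-record simple
random sample (per county, pooled over sexes); all other counties keep full
data, since only gold counties are scored. All four variants are refit per
sex and scored on (county × sex) pairs: the model estimate is the predicted
probability averaged over the county's full record composition (crude pooled
prevalence, matching the crude pooled gold standard — age standardization is
deliberately not applied here). Metrics: Lin's CCC with population moments,
signed mean relative error, RMSE. Selection: highest mean CCC across sample
sizes; exact ties broken by lower RMSE, then lower |MRE|. Down-sampling uses
a spawned bit-generator stream keyed by (seed, replicate, county, m), so the
grid reproduces bit-identically.

## Synthetic study conditions

The generator is the package's standing definition of the study conditions;
its defaults were fixed once, before the acceptance experiments were run.

* **Counties**: a rook-adjacency lattice stands in for the county adjacency
  graph. Race populations (~4–12k per county) vary smoothly and
  deterministically across the lattice so composition covariates have
  spatial structure.
* **County effects**: u_c = ρ·(neighbor mean of e) + (1−ρ)·e with e i.i.d.
  standard normal, rescaled to population SD exactly sd_u. Defaults
  sd_u = 0.5, ρ = 0.8 — strong, spatially smooth county heterogeneity, the
  regime in which a geospatial term is worth having. Moran's I of the
  effects verifiably increases with ρ.
* **Covariates**: per-county base values from realistic ranges (poverty
  ~N(0.15, 0.05) clipped, unemployment ~N(0.07, 0.02), percent rural
  uniform, PM2.5 ~N(10, 3), doctors ~N(250, 80)/100k), with small linear
  drifts in poverty, unemployment and physician rate so the change
  regression has real regressors.
* **Outcome surfaces**: obesity intercept −1.15 with rising trend
  (+0.055 logit/yr); any activity +1.35, flat; sufficient activity +0.20,
  +0.03/yr; age gradients peaking mid-life for obesity and declining for
  activity; modest race effects; covariate coefficients with conventional
  signs (poverty raises obesity, lowers activity, etc.).
* **Demographics**: age distribution (0.28, 0.19, 0.18, 0.16, 0.11, 0.08)
  over the six adult groups, sexes 50/50 — configurable; the within-county
  joint distribution of a real survey is not asserted.
* **Anthropometrics**: height is log-normal by sex; true BMI is drawn from a
  two-component shifted-gamma mixture *conditioned on the drawn obesity
  indicator* (obese: 30 + Γ(1.6, 3.0); non-obese: 30 − 0.5 − Γ(2.6, 1.9),
  clipped), so the binary outcome and the continuous BMI are consistent by
  construction; weight = BMI·height².
* **Reporting bias**: reported weight = scale·weight + (shift + noise)·h²,
  reported height = height + shift + noise. The additive weight component
  scales with frame size (h²), so the induced BMI distortion is uniform
  across statures: with zero height shift and zero noise, reported BMI =
  scale·true BMI + shift exactly — the structure the linear calibration can
  undo, making bias-parameter recovery well-posed. Defaults (scale 0.96,
  shift +0.8 BMI units, small noise) mimic modest under-reporting.
* **Activity minutes**: generated from the drawn sufficiency indicator
  (sufficient: 150 + Exp(90) moderate-equivalent minutes; insufficient:
  150·Beta(1.6, 1.2)), split into moderate/vigorous with a zero-inflated
  vigorous share — so recomputing sufficiency from minutes reproduces the
  drawn outcome for every record. Minutes are missing in even years by
  default (the odd-year questionnaire design); the any-activity response is
  asked every year. The generator does not force logical nesting between
  "any activity" and "sufficient activity" (the two survey questions measure
  different constructs), and it does not emulate telephone-frame selection,
  raking weights or nonresponse.
* **Examination cells**: superpopulation cell means are the analytic BMI
  mixture mean at the cell's population-average obesity prevalence, plus
  Gaussian sampling noise at the requested cell size (exact when the size is
  None). For exactness tests there is a records-matched variant that
  computes true-BMI cell means from the same generated sample — the
  noise-free synthetic examination survey for exactly that population.

All randomness flows from one explicit seed per call through a single
`numpy.random.Generator`; the generator touches no global state, and fixing
the seed fixes every generated byte.

What passing tests on this generator do **not** show: robustness to survey
weighting and nonresponse, to misreporting that varies in time or space, to
real county adjacency graphs (which are irregular), or to outcome
misclassification — none of which the generator emulates.

## Experiment sizes in the acceptance script and tests

Chosen as the package's scaled study conditions:

* Recovery: 10×10 grid, 80 records/county-year (≈200 per county, sex and
  five-year window), defaults sd_u = 0.5, ρ = 0.8; full variant. Expected:
  county prevalence correlation with truth > 0.9; time trend within 3 SE.
* Validation ranking: 8×8 grid; 16 spread gold counties at 380
  records/county-year (≈950 usable per county and sex over 2001–2005, over
  the 900 threshold) with 40/county-year elsewhere — a minority of
  high-sample counties among ordinary ones, mirroring the real design where
  only large counties qualify as gold; obesity, one sex, 25 replicates,
  m ∈ {10, 50, 100}. The full variant attains the best mean CCC at every m
  in our runs and is selected.
* Interval calibration: 20 replicates of a 6×6 grid at 150
  records/county-year under a generator configuration the naive model is
  exactly consistent with (no covariate effects, ρ = 0, identity reporting),
  500 draws — i.e. coverage is assessed under the model's own assumptions.
  Pooled coverage of nominal 95% intervals lands near 0.95 and is asserted
  within the loose 90–99% band that absorbs the Laplace and
  plug-in-σ̂ approximations.
* The change pipeline runs a 6×6 grid over 2001–2011 (seven windows, full
  variant, obesity and sufficient activity) and feeds the ecological
  regression; its coefficient on change in activity is reported
  descriptively (the generator draws the two outcomes' county effects
  independently, so its value is not calibrated to any published figure).

## Known limitations

* The Laplace likelihood slightly biases σ²ᵤ at very small cluster sizes
  (the classic Laplace/PQL limitation); intervals use σ̂ as plug-in, which
  the coverage band absorbs but does not eliminate.
* The geospatial term treats first-stage posterior means as known data — as
  specified — so second-stage standard errors do not propagate first-stage
  uncertainty.
* Annual estimates average overlapping windows with equal weights; a
  centered-window convention would differ at the series edges.
* The ecological regression is an unweighted area-level association with
  conventional OLS standard errors; no spatial-error structure, and no
  causal interpretation.
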