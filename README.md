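# countyprev

Small-area estimation of county-level obesity and physical-activity
prevalence from survey microdata.

State-based telephone surveillance surveys interview enough adults to say
something about every state, but most individual counties contribute only a
handful of respondents per year — far too few for direct county estimates.
`countyprev` implements a validated small-area pipeline that borrows strength
across counties, years and demographic groups to produce annual county
prevalence estimates (with uncertainty) for three binary outcomes: obesity
(BMI ≥ 30 kg/m²), any leisure-time physical activity, and *sufficient*
physical activity (≥ 150 moderate-equivalent minutes per week, one vigorous
minute counting as two moderate minutes). It is aimed at epidemiologists and
biostatisticians who want a tested, reusable and fully synthetic-data-driven
implementation of this class of methods.

## The method

**Self-report bias correction.** BMI is computed as weight (kg) / height²
(m²) from self-reported values, which are systematically biased. For every
two-year examination-survey cycle, mean BMI is computed by sex × age group in
both the self-report survey (reported) and the examination survey (measured),
and measured cell means are regressed on reported cell means separately per
sex. Each respondent's corrected BMI is `â + b̂ · reported BMI`; obesity is
classified from the corrected value.

**Small-area models.** For each outcome, sex and five-year moving window
(2001–2005, 2002–2006, …, 2007–2011) a logistic mixed model is fit:

```
logit P(y_ic = 1) = β₀ + race_i'βR + age_i'βA + δ·t + x_c'γ + θ·g_c + u_c,
u_c ~ N(0, σ²ᵤ)
```

Four nested variants are considered: **naive** (individual covariates, time
trend, county random intercept), **covariate** (adds county-level poverty,
unemployment, percent rural, education, PM2.5, racial composition, and — for
obesity — the doctors/dentists rate), **geospatial** (naive plus a geospatial
term `g_c`: the mean of the neighboring counties' posterior random-effect
means from a first-stage naive fit), and **full** (covariate plus a
geospatial term from a first-stage covariate fit). Fitting maximises a
Laplace approximation of the marginal likelihood, with the random-effect SD
profiled by a bounded scalar search; the joint Gaussian covariance over
(β, u) feeds the uncertainty simulation.

**Reporting.** Cell-level predictions (county × year × sex × age × race) are
collapsed to all-race estimates by county race-population weights and
age-standardized with the 2000 US census standard. Uncertainty comes from
pushing joint parameter draws through the same pipeline; 95% intervals are
percentile intervals, with draw indices shared across counties and years so
that differences (e.g. 2001→2009 change) are correctly correlated.

**Validation.** Counties with ≥ 900 pooled records in 2001–2005 serve as gold
standards (their direct pooled proportion). They are repeatedly down-sampled
to 10, 50 and 100 respondents, all four variants are refit, and estimates are
scored with Lin's concordance correlation coefficient, mean relative error
and RMSE; the best-concordance variant (the full model, in our experiments as
in the source validation studies) is selected for reporting.

**Change analysis.** County percentage-point changes between 2001 and 2009
are computed draw-wise, and an ecological OLS relates change in obesity to
change in sufficient activity, controlling for percent rural, changes in
poverty, unemployment and physician rate, and baseline obesity.

A seeded synthetic-data generator (`countyprev.synthetic`) produces survey
microdata with the structure the analysis assumes — spatially correlated
county effects on the logit scale, linear time trends, demographic
composition effects, affine self-report bias, odd-year-only detailed activity
minutes — so every stage is testable without restricted microdata.

## Worked example

```python
import numpy as np
from countyprev import synthetic as syn, calibration as cal, outcomes as oc
from countyprev import models as mdl, aggregation as agg

counties = syn.make_county_grid(4, 4)
truth = syn.simulate_truth(counties, range(2001, 2006), syn.GenerativeParams(seed=1))
records = syn.simulate_survey(truth, counties, 150, seed=2)

cycles = [(2001, 2002), (2003, 2004)]
calib = cal.fit_calibration(
    cal.reported_cells(records, cycles),
    syn.examination_cells_from_records(records, cycles),
)
print("calibration (female):", dict(zip(("intercept", "slope"),
      (round(v, 3) for v in calib.coefficients["female"]))))
data = oc.derive_outcomes(records, calib)
fit = mdl.fit_variant(data, counties,
                      mdl.ModelSpec("full", "obesity", "female", (2001, 2005)))

std = agg.us_standard_2000()
cube = agg.simulate_uncertainty(fit, counties, std, n_draws=1000, seed=3)
est = agg.summarize_cube(cube, "female", "obesity")
row = est[(est.county_id == "c00_00") & (est.year == 2003)].iloc[0]
print(f"county c00_00, 2003: {100*row['mean']:.1f}% "
      f"(95% UI {100*row['lower']:.1f}-{100*row['upper']:.1f})")
```

prints

```
calibration (female): {'intercept': -0.561, 'slope': 1.038}
county c00_00, 2003: 29.1% (95% UI 25.1-34.1)
```

i.e. the per-sex calibration line mapping reported to measured BMI, and an
age-standardized, all-race obesity prevalence of 29.1% for one county with
its simulated 95% uncertainty interval (the generating truth for that county
is 29.8%).

The same pipeline is available from the shell:

```bash
countyprev simulate --rows 8 --cols 8 --n 200 --seed 7 --outdir simdata
countyprev correct --microdata simdata/microdata.csv \
    --exam-cells simdata/examination_cells.csv --outdir simdata
countyprev outcomes --microdata simdata/microdata.csv \
    --calibration simdata/calibration.json --out simdata/derived.csv
countyprev validate --microdata simdata/derived.csv --county-dir simdata \
    --outcome obesity --reps 25 --seed 7 --outdir simdata
countyprev estimate --microdata simdata/derived.csv --county-dir simdata \
    --outcome obesity --sex female --variant full --out simdata/estimates.csv
```

Every command writes a manifest (configuration hash, seed, input/output
digests) alongside its outputs, so identical configurations provably produce
identical results.

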