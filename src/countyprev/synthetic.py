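"""Seeded synthetic survey microdata with county-clustered spatial structure.

This module emulates the statistical structure that the small-area analysis
assumes, so that every downstream stage (self-report calibration, outcome
definitions, mixed-model fitting, poststratification, validation and the
ecological change regression) can be exercised and tested without access to
restricted survey microdata:

* counties on a lattice with rook adjacency, carrying per-year socioeconomic
  covariates and race-specific populations;
* three binary outcomes (obesity, any physical activity, sufficient physical
  activity) generated from logistic truth surfaces with age, race and sex
  effects, a linear time trend, county covariate effects, and spatially
  correlated county random effects on the logit scale;
* self-reported height and weight distorted by a configurable reporting bias;
* detailed activity minutes that are consistent with each respondent's drawn
  sufficiency outcome and, by default, observed only in odd survey years;
* examination-survey reference cells (measured BMI means) for the
  bias-correction fit.

All randomness flows from a single explicit seed per call through one
``numpy.random.Generator``; nothing touches global random state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "AGE_GROUPS",
    "RACES",
    "SEXES",
    "COUNTY_COVARIATES",
    "OUTCOMES",
    "CountyTable",
    "OutcomeParams",
    "GenerativeParams",
    "ReportingBias",
    "TruthSurface",
    "make_county_grid",
    "simulate_truth",
    "simulate_survey",
    "simulate_examination_cells",
    "examination_cells_from_records",
    "default_nhanes_cycles",
]

AGE_GROUPS = ("20-34", "35-44", "45-54", "55-64", "65-74", "75+")
RACES = ("white", "black", "hispanic", "native_american", "other")
SEXES = ("male", "female")
OUTCOMES = ("obesity", "any_pa", "sufficient_pa")

#: County-level covariates carried by :class:`CountyTable`. Proportions are on
#: [0, 1]; ``pm25`` is a concentration in arbitrary units; ``docs_per_100k`` a
#: rate per 100,000 population.
COUNTY_COVARIATES = (
    "poverty",
    "unemployment",
    "pct_rural",
    "pct_hs_diploma",
    "pm25",
    "docs_per_100k",
)

# Adult age composition used to draw respondent ages (roughly the US adult
# age structure; configurable through GenerativeParams.age_distribution).
DEFAULT_AGE_DISTRIBUTION = (0.28, 0.19, 0.18, 0.16, 0.11, 0.08)

# BMI mixture used to generate anthropometrics conditional on the drawn
# obesity indicator: obese BMI = 30 + Gamma(k, theta), non-obese
# BMI = 30 - (0.5 + Gamma(k, theta)). The 0.5 offset keeps the indicator and
# the continuous BMI consistent on both sides of the threshold.
_OBESE_GAMMA = (1.6, 3.0)       # mean 4.8 above 30
_NONOBESE_GAMMA = (2.6, 1.9)    # mean 4.94 + 0.5 below 30
_NONOBESE_OFFSET = 0.5

_HEIGHT_LOGMEAN = {"male": np.log(1.76), "female": np.log(1.62)}
_HEIGHT_LOGSD = {"male": 0.040, "female": 0.041}


def bmi_mixture_moments(p_obese):
    """Mean and variance of the BMI mixture at obesity prevalence ``p_obese``.

    Used both by the examination-cell generator (superpopulation cell means)
    and by tests that need an analytic reference.
    """
    p = np.asarray(p_obese, dtype=float)
    k1, t1 = _OBESE_GAMMA
    k0, t0 = _NONOBESE_GAMMA
    m1 = 30.0 + k1 * t1
    m0 = 30.0 - (_NONOBESE_OFFSET + k0 * t0)
    v1 = k1 * t1**2
    v0 = k0 * t0**2
    mean = p * m1 + (1.0 - p) * m0
    var = p * (v1 + (m1 - mean) ** 2) + (1.0 - p) * (v0 + (m0 - mean) ** 2)
    return mean, var


# ---------------------------------------------------------------------------
# County structure
# ---------------------------------------------------------------------------


@dataclass
class CountyTable:
    """County identifiers, adjacency, per-year covariates and race populations.

    ``covariates`` is indexed by (county_id, year) with one column per entry of
    :data:`COUNTY_COVARIATES`; it may be empty until :func:`simulate_truth`
    (or a file reader) populates it. ``race_populations`` is indexed by
    county_id with one column per race.
    """

    county_ids: list
    neighbors: dict
    covariates: pd.DataFrame
    race_populations: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self):
        ids = set(self.county_ids)
        if len(ids) != len(self.county_ids):
            raise ValueError("duplicate county ids")
        for c, nbrs in self.neighbors.items():
            if c not in ids:
                raise ValueError(f"neighbor map references unknown county {c!r}")
            if c in nbrs:
                raise ValueError(f"county {c!r} listed as its own neighbor")
            for b in nbrs:
                if c not in self.neighbors.get(b, ()):  # symmetry
                    raise ValueError(f"adjacency not symmetric for ({c!r}, {b!r})")
        rp = self.race_populations
        if not rp.empty:
            if (rp.values < 0).any():
                raise ValueError("race populations must be non-negative")
            if (rp.sum(axis=1) <= 0).any():
                raise ValueError("every county needs positive total population")
        cov = self.covariates
        if not cov.empty:
            prop_cols = [c for c in ("poverty", "unemployment", "pct_rural", "pct_hs_diploma") if c in cov]
            sub = cov[prop_cols]
            if ((sub < 0) | (sub > 1)).any().any():
                raise ValueError("covariate proportions must lie in [0, 1]")

    @property
    def race_shares(self):
        """Race composition per county (rows sum to 1)."""
        rp = self.race_populations
        return rp.div(rp.sum(axis=1), axis=0)

    def covariate_lookup(self, county_ids, years, column):
        """Vector of covariate values for parallel (county, year) arrays."""
        idx = pd.MultiIndex.from_arrays([county_ids, years])
        return self.covariates[column].reindex(idx).to_numpy()


def make_county_grid(rows, cols):
    """Lattice of ``rows`` x ``cols`` counties with rook (edge-sharing) adjacency.

    Covariates start empty; race populations are a deterministic smooth
    function of grid position (total ~10,000 persons per county) so that
    racial-composition covariates vary across the map. Deterministic given
    (rows, cols).
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    ids = [f"c{r:02d}_{c:02d}" for r in range(rows) for c in range(cols)]
    neighbors = {}
    for r in range(rows):
        for c in range(cols):
            nbrs = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    nbrs.append(f"c{rr:02d}_{cc:02d}")
            neighbors[f"c{r:02d}_{c:02d}"] = frozenset(nbrs)

    rows_t = np.repeat(np.linspace(0.0, 1.0, rows) if rows > 1 else [0.5], cols)
    cols_t = np.tile(np.linspace(0.0, 1.0, cols) if cols > 1 else [0.5], rows)
    raw = np.column_stack(
        [
            6.0 + 2.0 * rows_t,                       # white
            0.8 + 2.2 * cols_t,                       # black
            0.8 + 2.0 * (1.0 - rows_t) * (0.4 + cols_t),  # hispanic
            0.15 + 0.4 * rows_t * (1.0 - cols_t),     # native_american
            0.5 + 1.0 * rows_t * cols_t,              # other
        ]
    )
    shares = raw / raw.sum(axis=1, keepdims=True)
    totals = np.round(8000 + 4000 * (0.5 + 0.5 * np.sin(3.1 * rows_t) * np.cos(2.3 * cols_t)))
    pops = np.round(shares * totals[:, None]).astype(int)
    pops = np.maximum(pops, 1)
    race_populations = pd.DataFrame(pops, index=pd.Index(ids, name="county_id"), columns=list(RACES))

    covariates = pd.DataFrame(
        columns=list(COUNTY_COVARIATES),
        index=pd.MultiIndex.from_arrays([[], []], names=["county_id", "year"]),
        dtype=float,
    )
    return CountyTable(ids, neighbors, covariates, race_populations)


# ---------------------------------------------------------------------------
# Generative parameters and truth surfaces
# ---------------------------------------------------------------------------


@dataclass
class OutcomeParams:
    """Logit-scale generative settings for one binary outcome."""

    intercept: float
    sex_effects: dict
    age_effects: dict
    race_effects: dict
    time_slope: float
    covariate_coefs: dict
    sd_u: float = 0.5
    rho: float = 0.8

    def zeroed(self, **overrides):
        """Copy with all effects except the intercept set to zero (test helper)."""
        out = replace(
            self,
            sex_effects={s: 0.0 for s in SEXES},
            age_effects={a: 0.0 for a in AGE_GROUPS},
            race_effects={r: 0.0 for r in RACES},
            time_slope=0.0,
            covariate_coefs={c: 0.0 for c in COUNTY_COVARIATES},
            sd_u=0.0,
            rho=0.0,
        )
        return replace(out, **overrides)


def _default_outcomes():
    ages = AGE_GROUPS
    return {
        "obesity": OutcomeParams(
            intercept=-1.15,
            sex_effects={"male": 0.0, "female": -0.05},
            age_effects=dict(zip(ages, (0.0, 0.35, 0.50, 0.55, 0.45, 0.10))),
            race_effects=dict(zip(RACES, (0.0, 0.45, 0.25, 0.55, 0.05))),
            time_slope=0.055,
            covariate_coefs={
                "poverty": 1.2,
                "unemployment": 0.8,
                "pct_rural": 0.30,
                "pct_hs_diploma": -0.6,
                "pm25": 0.010,
                "docs_per_100k": -0.0006,
            },
        ),
        "any_pa": OutcomeParams(
            intercept=1.35,
            sex_effects={"male": 0.0, "female": -0.25},
            age_effects=dict(zip(ages, (0.0, -0.10, -0.20, -0.35, -0.50, -0.90))),
            race_effects=dict(zip(RACES, (0.0, -0.40, -0.50, -0.45, -0.20))),
            time_slope=0.0,
            covariate_coefs={
                "poverty": -1.0,
                "unemployment": -0.6,
                "pct_rural": -0.20,
                "pct_hs_diploma": 0.8,
                "pm25": -0.010,
                "docs_per_100k": 0.0,
            },
        ),
        "sufficient_pa": OutcomeParams(
            intercept=0.20,
            sex_effects={"male": 0.0, "female": -0.20},
            age_effects=dict(zip(ages, (0.0, -0.10, -0.20, -0.30, -0.40, -0.70))),
            race_effects=dict(zip(RACES, (0.0, -0.30, -0.35, -0.30, -0.15))),
            time_slope=0.030,
            covariate_coefs={
                "poverty": -1.0,
                "unemployment": -0.6,
                "pct_rural": -0.20,
                "pct_hs_diploma": 0.8,
                "pm25": -0.010,
                "docs_per_100k": 0.0,
            },
        ),
    }


@dataclass
class GenerativeParams:
    """Settings for :func:`simulate_truth`.

    The defaults are the package's standing study conditions: spatially
    correlated county effects (SD 0.5, mixing weight rho 0.8 on the logit
    scale), realistic covariate distributions with mild linear drift, a
    rising obesity trend and a mildly rising sufficient-activity trend.
    """

    seed: int = 0
    outcomes: dict = field(default_factory=_default_outcomes)
    age_distribution: tuple = DEFAULT_AGE_DISTRIBUTION
    female_share: float = 0.5

    def __post_init__(self):
        for name, op in self.outcomes.items():
            if not 0.0 <= op.rho <= 1.0:
                raise ValueError(f"rho for outcome {name!r} must lie in [0, 1]")
            if op.sd_u < 0:
                raise ValueError(f"sd_u for outcome {name!r} must be non-negative")
        if abs(sum(self.age_distribution) - 1.0) > 1e-9:
            raise ValueError("age_distribution must sum to 1")


@dataclass
class ReportingBias:
    """Self-report distortion of weight and height.

    reported_weight = weight_scale * true_weight
                      + (weight_shift + N(0, weight_noise_sd)) * true_height**2
    reported_height = true_height + height_shift + N(0, height_noise_sd)

    The additive weight component scales with frame size (height squared), so
    the distortion it induces on the BMI scale is uniform across statures:
    with ``height_shift = 0`` and no noise,
    reported BMI = weight_scale * true BMI + weight_shift exactly, which is
    the structure the per-sex linear calibration can undo. ``weight_shift``
    is therefore expressed in BMI units (kg/m^2).
    """

    weight_scale: float = 0.96
    weight_shift: float = 0.8
    height_shift: float = 0.005
    weight_noise_sd: float = 0.6
    height_noise_sd: float = 0.005

    @classmethod
    def none(cls):
        """Identity reporting (no distortion, no noise)."""
        return cls(1.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class TruthSurface:
    """True logit-scale components and prevalences for every outcome.

    Houses the generative county random effects ``u_c`` and the linear time
    trend; the estimation models in :mod:`countyprev.models` are the
    inferential counterpart of this structure.
    """

    years: tuple
    year_center: float
    params: GenerativeParams
    u: dict                 # outcome -> pd.Series over counties
    counties: CountyTable

    def linear_predictor(self, outcome, county_ids, years, sexes, age_groups, races):
        """Vectorised logit of the true prevalence for parallel label arrays."""
        op = self.params.outcomes[outcome]
        county_ids = np.asarray(county_ids, dtype=object)
        years = np.asarray(years)
        eta = np.full(county_ids.shape, op.intercept, dtype=float)
        eta += np.asarray(pd.Series(sexes).map(op.sex_effects))
        eta += np.asarray(pd.Series(age_groups).map(op.age_effects))
        eta += np.asarray(pd.Series(races).map(op.race_effects))
        eta += op.time_slope * (years - self.year_center)
        for cov, coef in op.covariate_coefs.items():
            if coef != 0.0:
                eta += coef * self.counties.covariate_lookup(county_ids, years, cov)
        eta += self.u[outcome].reindex(county_ids).to_numpy()
        return eta

    def prevalence(self, outcome, county_ids, years, sexes, age_groups, races):
        from scipy.special import expit

        return expit(self.linear_predictor(outcome, county_ids, years, sexes, age_groups, races))

    def cell_grid(self, years=None):
        """All (county, year, sex, age_group, race) label combinations."""
        years = list(years if years is not None else self.years)
        rows = list(itertools.product(self.counties.county_ids, years, SEXES, AGE_GROUPS, RACES))
        return pd.DataFrame(rows, columns=["county_id", "year", "sex", "age_group", "race"])

    def county_prevalence(self, outcome, year, sex, age_weights=None):
        """True all-race prevalence per county at one year and sex.

        Race groups are weighted by the county race populations; age groups by
        ``age_weights`` (a mapping), defaulting to the generator's respondent
        age distribution (i.e. the crude composition).
        """
        if age_weights is None:
            age_weights = dict(zip(AGE_GROUPS, self.params.age_distribution))
        grid = self.cell_grid(years=[year])
        grid = grid[grid["sex"] == sex].reset_index(drop=True)
        p = self.prevalence(
            outcome, grid["county_id"], grid["year"], grid["sex"], grid["age_group"], grid["race"]
        )
        shares = self.counties.race_shares
        w_race = shares.to_numpy()[
            pd.Index(self.counties.county_ids).get_indexer(grid["county_id"]),
            pd.Index(shares.columns).get_indexer(grid["race"]),
        ]
        w_age = grid["age_group"].map(age_weights).to_numpy()
        grid = grid.assign(wp=p * w_race * w_age, w=w_race * w_age)
        agg = grid.groupby("county_id")[["wp", "w"]].sum()
        return (agg["wp"] / agg["w"]).reindex(self.counties.county_ids)


def _spatial_effects(counties, sd, rho, rng):
    """County effects as a convex mix of i.i.d. noise and its neighbor mean.

    ``u_raw = rho * neighbor_mean(e) + (1 - rho) * e`` with e ~ N(0, 1),
    rescaled so the delivered effects have (population) SD exactly ``sd``.
    """
    ids = list(counties.county_ids)
    e = rng.standard_normal(len(ids))
    if sd == 0.0:
        return pd.Series(0.0, index=ids)
    pos = {c: i for i, c in enumerate(ids)}
    nbr_mean = np.zeros(len(ids))
    for i, c in enumerate(ids):
        nbrs = counties.neighbors.get(c, ())
        if nbrs:
            nbr_mean[i] = np.mean([e[pos[b]] for b in nbrs])
    u = rho * nbr_mean + (1.0 - rho) * e
    s = u.std()
    if s > 0:
        u = u * (sd / s)
    return pd.Series(u, index=ids)


def simulate_truth(counties, years, params):
    """Draw covariates and county effects; return the true prevalence surface.

    If ``counties.covariates`` is empty it is populated in place with seeded
    per-county base values plus a small linear drift over ``years`` (poverty,
    unemployment and the doctors rate drift; the others are held fixed).
    Reproducible for a fixed ``params.seed``.
    """
    years = tuple(years)
    if not years:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(params.seed)
    n = len(counties.county_ids)

    if counties.covariates.empty:
        base = {
            "poverty": np.clip(rng.normal(0.15, 0.05, n), 0.02, 0.5),
            "unemployment": np.clip(rng.normal(0.07, 0.02, n), 0.01, 0.3),
            "pct_rural": rng.uniform(0.0, 1.0, n),
            "pct_hs_diploma": np.clip(rng.normal(0.84, 0.06, n), 0.5, 0.99),
            "pm25": np.clip(rng.normal(10.0, 3.0, n), 2.0, 25.0),
            "docs_per_100k": np.clip(rng.normal(250.0, 80.0, n), 30.0, 900.0),
        }
        drift = {
            "poverty": rng.normal(0.0, 0.004, n),
            "unemployment": rng.normal(0.001, 0.003, n),
            "pct_rural": np.zeros(n),
            "pct_hs_diploma": np.zeros(n),
            "pm25": np.zeros(n),
            "docs_per_100k": rng.normal(0.0, 3.0, n),
        }
        y0 = years[0]
        frames = []
        for y in years:
            row = {c: base[c] + drift[c] * (y - y0) for c in COUNTY_COVARIATES}
            df = pd.DataFrame(row)
            df["poverty"] = df["poverty"].clip(0.0, 1.0)
            df["unemployment"] = df["unemployment"].clip(0.0, 1.0)
            df["pct_hs_diploma"] = df["pct_hs_diploma"].clip(0.0, 1.0)
            df["docs_per_100k"] = df["docs_per_100k"].clip(lower=1.0)
            df["county_id"] = counties.county_ids
            df["year"] = y
            frames.append(df)
        cov = pd.concat(frames, ignore_index=True).set_index(["county_id", "year"])
        counties.covariates = cov[list(COUNTY_COVARIATES)]
        counties.validate()

    year_center = (years[0] + years[-1]) / 2.0
    u = {}
    for name, op in params.outcomes.items():
        if not 0.0 <= op.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        u[name] = _spatial_effects(counties, op.sd_u, op.rho, rng)
    return TruthSurface(years=years, year_center=year_center, params=params, u=u, counties=counties)


# ---------------------------------------------------------------------------
# Survey microdata
# ---------------------------------------------------------------------------


def simulate_survey(
    truth,
    counties,
    n_per_county_year,
    reporting_bias=None,
    seed=0,
    odd_year_minutes_only=True,
    p_missing_demographics=0.0,
):
    """Generate individual survey records for every county and truth year.

    Demographics are drawn from the county race populations and the
    generator's age/sex distribution; each binary outcome is Bernoulli at its
    true prevalence; anthropometrics come from the BMI mixture conditioned on
    the drawn obesity indicator; detailed activity minutes are generated to be
    exactly consistent with the drawn sufficiency outcome; and, when
    ``odd_year_minutes_only`` is set, the minutes fields are missing in even
    survey years (emulating the detailed questionnaire appearing only in
    odd-numbered years).

    ``n_per_county_year`` may be a single integer or a mapping/Series from
    county id to integer, emulating the very uneven county sample sizes of a
    real surveillance survey.

    Columns prefixed ``true_`` carry generator-internal truth used by tests
    and validation experiments; the file writer keeps them optional.
    """
    county_ids = list(counties.county_ids)
    if isinstance(n_per_county_year, (int, np.integer)):
        n_by_county = {c: int(n_per_county_year) for c in county_ids}
    else:
        n_by_county = {c: int(pd.Series(n_per_county_year).get(c, 0)) for c in county_ids}
    if any(v < 0 for v in n_by_county.values()):
        raise ValueError("n_per_county_year must be non-negative")
    bias = reporting_bias if reporting_bias is not None else ReportingBias()
    rng = np.random.default_rng(seed)
    params = truth.params

    cols = [
        "year", "county_id", "sex", "age_group", "race",
        "reported_weight", "reported_height",
        "any_pa", "moderate_min_week", "vigorous_min_week",
        "true_bmi", "true_obese", "true_any_pa", "true_sufficient_pa",
    ]
    years = list(truth.years)
    n_total = sum(n_by_county.values()) * len(years)
    if n_total == 0:
        return pd.DataFrame(columns=cols)

    county = np.repeat(
        np.array(county_ids, dtype=object), [len(years) * n_by_county[c] for c in county_ids]
    )
    year = np.concatenate(
        [np.repeat(years, n_by_county[c]) for c in county_ids if n_by_county[c] > 0]
    )

    sex = np.where(rng.random(n_total) < params.female_share, "female", "male").astype(object)
    age = rng.choice(np.array(AGE_GROUPS, dtype=object), size=n_total, p=list(params.age_distribution))

    shares = counties.race_shares.reindex(county_ids).to_numpy()
    cum = np.cumsum(shares, axis=1)
    county_pos = pd.Index(county_ids).get_indexer(county)
    draw = rng.random(n_total)
    race_idx = (draw[:, None] > cum[county_pos]).sum(axis=1)
    race = np.array(RACES, dtype=object)[race_idx]

    p = {
        out: truth.prevalence(out, county, year, sex, age, race)
        for out in OUTCOMES
    }
    obese = rng.random(n_total) < p["obesity"]
    any_pa = rng.random(n_total) < p["any_pa"]
    sufficient = rng.random(n_total) < p["sufficient_pa"]

    # anthropometrics ------------------------------------------------------
    k1, t1 = _OBESE_GAMMA
    k0, t0 = _NONOBESE_GAMMA
    bmi = np.where(
        obese,
        30.0 + rng.gamma(k1, t1, n_total),
        30.0 - (_NONOBESE_OFFSET + np.minimum(rng.gamma(k0, t0, n_total), 13.0)),
    )
    logmean = pd.Series(sex).map(_HEIGHT_LOGMEAN).to_numpy()
    logsd = pd.Series(sex).map(_HEIGHT_LOGSD).to_numpy()
    height = np.exp(rng.normal(logmean, logsd))
    weight = bmi * height**2

    rep_weight = (
        bias.weight_scale * weight
        + (bias.weight_shift + rng.normal(0.0, bias.weight_noise_sd, n_total)) * height**2
    )
    rep_height = height + bias.height_shift + rng.normal(0.0, bias.height_noise_sd, n_total)

    # activity minutes, consistent with the drawn sufficiency outcome ------
    total_me = np.where(
        sufficient,
        150.0 + rng.exponential(90.0, n_total),
        150.0 * rng.beta(1.6, 1.2, n_total),
    )
    vig_share = np.where(rng.random(n_total) < 0.55, 0.0, rng.beta(0.8, 2.5, n_total))
    vigorous = total_me * vig_share / 2.0
    moderate = total_me - 2.0 * vigorous

    df = pd.DataFrame(
        {
            "year": year,
            "county_id": county,
            "sex": sex,
            "age_group": age,
            "race": race,
            "reported_weight": rep_weight,
            "reported_height": rep_height,
            "any_pa": np.where(any_pa, "yes", "no"),
            "moderate_min_week": moderate,
            "vigorous_min_week": vigorous,
            "true_bmi": bmi,
            "true_obese": obese.astype(int),
            "true_any_pa": any_pa.astype(int),
            "true_sufficient_pa": sufficient.astype(int),
        }
    )

    if odd_year_minutes_only:
        hidden = (df["year"] % 2 == 0) & (df["year"] < 2012)
        df.loc[hidden, ["moderate_min_week", "vigorous_min_week"]] = np.nan

    if p_missing_demographics > 0:
        for col in ("sex", "age_group", "race", "county_id"):
            mask = rng.random(n_total) < p_missing_demographics
            df.loc[mask, col] = np.nan

    return df


# ---------------------------------------------------------------------------
# Examination-survey reference cells
# ---------------------------------------------------------------------------


def default_nhanes_cycles(first=2001, last=2010):
    """Two-year examination cycles covering [first, last]."""
    return [(y, y + 1) for y in range(first, last, 2)]


def simulate_examination_cells(truth, cycles, n_per_cell=None, seed=0):
    """Measured (undistorted) BMI cell means per (cycle, sex, age group).

    The superpopulation cell mean is the BMI-mixture mean at the
    population-average obesity prevalence for the cell (county race
    populations weighting counties and races, cycle years averaged). With
    ``n_per_cell=None`` the means are exact; otherwise Gaussian sampling noise
    with the mixture standard error for a sample of that size is added.
    """
    cycles = list(cycles)
    if not cycles:
        raise ValueError("cycles must be non-empty")
    rng = np.random.default_rng(seed)
    counties = truth.counties
    pops = counties.race_populations
    county_w = pops.sum(axis=1) / pops.values.sum()
    shares = counties.race_shares

    rows = []
    for (y0, y1) in cycles:
        cyc_years = [y for y in (y0, y1) if y in truth.years]
        if not cyc_years:
            continue
        for sex in SEXES:
            for age in AGE_GROUPS:
                grid = truth.cell_grid(years=cyc_years)
                grid = grid[(grid["sex"] == sex) & (grid["age_group"] == age)].reset_index(drop=True)
                p = truth.prevalence(
                    "obesity", grid["county_id"], grid["year"], grid["sex"],
                    grid["age_group"], grid["race"],
                )
                w = (
                    county_w.reindex(grid["county_id"]).to_numpy()
                    * shares.to_numpy()[
                        pd.Index(counties.county_ids).get_indexer(grid["county_id"]),
                        pd.Index(shares.columns).get_indexer(grid["race"]),
                    ]
                )
                p_bar = float(np.average(p, weights=w))
                mean, var = bmi_mixture_moments(p_bar)
                n = np.nan
                if n_per_cell is not None:
                    mean = mean + rng.normal(0.0, np.sqrt(var / n_per_cell))
                    n = n_per_cell
                rows.append(
                    {
                        "cycle_start": y0, "cycle_end": y1, "sex": sex,
                        "age_group": age, "mean_bmi": float(mean), "n": n,
                    }
                )
    if not rows:
        raise DataError("no examination cycle overlaps the truth years")
    return pd.DataFrame(rows)


def examination_cells_from_records(records, cycles):
    """Noise-free synthetic examination cells matched to generated records.

    Computes the mean *true* BMI per (cycle, sex, age group) from the
    generator's hidden ``true_bmi`` column — the examination-survey analogue
    for the exact same sampled population, used by round-trip tests of the
    calibration stage.
    """
    if "true_bmi" not in records:
        raise DataError("records lack the generator's true_bmi column")
    rows = []
    for (y0, y1) in cycles:
        sub = records[(records["year"] >= y0) & (records["year"] <= y1)]
        if sub.empty:
            continue
        g = sub.groupby(["sex", "age_group"], observed=True)["true_bmi"].agg(["mean", "size"])
        for (sex, age), r in g.iterrows():
            rows.append(
                {
                    "cycle_start": y0, "cycle_end": y1, "sex": sex,
                    "age_group": age, "mean_bmi": r["mean"], "n": int(r["size"]),
                }
            )
    return pd.DataFrame(rows)
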