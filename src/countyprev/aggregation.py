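"""Poststratification and simulated uncertainty for reported prevalences.

Cell-level model predictions (county x year x sex x age group x race) are
turned into the reported quantities in two convex-combination steps: race
groups are collapsed with county race-population weights (poststratification)
and age groups with a fixed standard population (direct age standardization;
the 2000 US census standard ships as a data asset). Uncertainty is propagated
by simulation: parameter vectors (fixed effects and county random effects
jointly) are drawn from the fit's Gaussian covariance approximation, every
draw is pushed through the same predict -> aggregate pipeline, and 95%
intervals are the 2.5th/97.5th percentiles of the resulting draw sets. Draw
indices are shared across counties and years, so downstream differences
(e.g. 2001 to 2009 change) inherit the correct correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import SchemaError
from .models import _cell_matrix, combine_windows
from .synthetic import AGE_GROUPS, RACES

__all__ = [
    "StandardPopulation",
    "us_standard_2000",
    "aggregate_race",
    "age_standardize",
    "parameter_draws",
    "simulate_uncertainty",
    "estimate_prevalence",
    "DrawsCube",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardPopulation:
    """Age-standardization weights (one per age group, summing to one)."""

    weights: dict

    def __post_init__(self):
        w = self.weights
        if any(v < 0 for v in w.values()):
            raise ValueError("standard population weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("standard population weights must sum to 1")

    @classmethod
    def from_counts(cls, counts):
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValueError("standard population counts must sum > 0")
        return cls({k: v / total for k, v in counts.items()})


def us_standard_2000():
    """The 2000 US census adult age structure as a standard population."""
    path = resources.files("countyprev").joinpath("data/us_standard_2000.csv")
    with resources.as_file(path) as f:
        df = pd.read_csv(f)
    return StandardPopulation.from_counts(dict(zip(df["age_group"], df["population"])))


def aggregate_race(predictions, race_populations):
    """Population-weighted average of race-specific estimates.

    ``predictions`` and ``race_populations`` are mappings (or Series) over the
    same race set; weights are pop_r / sum(pop).
    """
    p = pd.Series(predictions, dtype=float)
    pop = pd.Series(race_populations, dtype=float)
    if set(p.index) != set(pop.index):
        raise SchemaError(
            f"race sets differ: predictions {sorted(p.index)} vs populations {sorted(pop.index)}"
        )
    total = pop.sum()
    if total <= 0:
        raise ValueError("race populations must sum to a positive total")
    return float((p * pop.reindex(p.index)).sum() / total)


def age_standardize(predictions, standard):
    """Directly age-standardized prevalence: sum_a w_a p_a.

    Every age group carried by the standard must be present in the
    predictions.
    """
    p = pd.Series(predictions, dtype=float)
    missing = [a for a in standard.weights if a not in p.index or pd.isna(p[a])]
    if missing:
        raise SchemaError(f"age group(s) missing from predictions: {missing}")
    return float(sum(w * p[a] for a, w in standard.weights.items()))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _psd_factor(cov, repair=True):
    """Cholesky-like factor L with cov = L L', flooring negative eigenvalues."""
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-8:
        if not repair:
            raise np.linalg.LinAlgError(
                f"covariance not positive semidefinite (min eigenvalue {vals.min():.3g})"
            )
        logger.warning(
            "covariance repaired by eigenvalue flooring (min eigenvalue %.3g)", vals.min()
        )
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def parameter_draws(fit, county_ids, n_draws, rng, repair=True):
    """Joint Gaussian draws of (beta, u) for every county in ``county_ids``.

    Counties absent from the fit get independent N(0, sigma2_u) draws — the
    empirical-Bayes prior for a county contributing no data.

    Returns (beta_draws [n_draws x p], u_draws [n_draws x n_counties]).
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    p = len(fit.beta)
    mean = np.concatenate([fit.beta, fit.u.to_numpy()])
    L = _psd_factor(fit.cov, repair=repair)
    z = rng.standard_normal((n_draws, len(mean)))
    theta = mean + z @ L.T
    beta_draws = theta[:, :p]

    u_draws = np.zeros((n_draws, len(county_ids)))
    pos = pd.Index(county_ids).get_indexer(fit.u.index)
    u_draws[:, pos[pos >= 0]] = theta[:, p:][:, pos >= 0]
    missing = [i for i, c in enumerate(county_ids) if c not in fit.u.index]
    if missing:
        sd = np.sqrt(max(fit.sigma2_u, 0.0))
        u_draws[:, missing] = rng.standard_normal((n_draws, len(missing))) * sd
    return beta_draws, u_draws


@dataclass
class DrawsCube:
    """Aligned prevalence draws: array[county, year, draw] on the probability scale."""

    county_ids: list
    years: list
    array: np.ndarray

    def at(self, county_id, year):
        return self.array[self.county_ids.index(county_id), self.years.index(year), :]


def _cell_weights(cells, counties, standard):
    """Per-cell weight w_age * race_share; sums to 1 within each county-year."""
    w_age = cells["age_group"].map(standard.weights).to_numpy(dtype=float)
    shares = counties.race_shares
    w_race = shares.to_numpy()[
        pd.Index(shares.index).get_indexer(cells["county_id"]),
        pd.Index(shares.columns).get_indexer(cells["race"]),
    ]
    return w_age * w_race


def simulate_uncertainty(fit, counties, standard, n_draws=1000, seed=0, years=None, repair=True):
    """All-race, age-standardized county-year prevalence draws for one fit.

    Returns a :class:`DrawsCube` over every county in the table and the
    requested years (default: the fit's window). The same draw index refers to
    the same parameter draw in every county and year.
    """
    spec = fit.spec
    years = list(years) if years is not None else list(range(spec.window[0], spec.window[1] + 1))
    county_ids = list(counties.county_ids)
    rng = np.random.default_rng(seed)
    beta_draws, u_draws = parameter_draws(fit, county_ids, n_draws, rng, repair=repair)

    cells = pd.DataFrame(
        itertools.product(county_ids, years, AGE_GROUPS, RACES),
        columns=["county_id", "year", "age_group", "race"],
    )
    X, _ = _cell_matrix(cells, counties, spec, fit.geo_term, spec.year_center)
    w = _cell_weights(cells, counties, standard)
    pos = pd.Index(county_ids).get_indexer(cells["county_id"])

    eta = X @ beta_draws.T + u_draws.T[pos, :]
    P = expit(eta) * w[:, None]
    block = len(AGE_GROUPS) * len(RACES)
    starts = np.arange(0, len(cells), block)
    agg = np.add.reduceat(P, starts, axis=0)  # (county*year, draws)
    cube = agg.reshape(len(county_ids), len(years), n_draws)
    return DrawsCube(county_ids, years, cube)


def summarize_cube(cube, sex, outcome, n_draws=None):
    """Percentile summary of a draws cube as a tidy estimates frame."""
    arr = cube.array
    mean = arr.mean(axis=2)
    lower = np.percentile(arr, 2.5, axis=2)
    upper = np.percentile(arr, 97.5, axis=2)
    rows = []
    for i, c in enumerate(cube.county_ids):
        for j, y in enumerate(cube.years):
            rows.append(
                {
                    "county_id": c,
                    "year": y,
                    "sex": sex,
                    "outcome": outcome,
                    "mean": mean[i, j],
                    "lower": lower[i, j],
                    "upper": upper[i, j],
                    "n_draws": n_draws or arr.shape[2],
                }
            )
    return pd.DataFrame(rows)


def estimate_prevalence(fits, counties, standard, n_draws=1000, seed=0, repair=True):
    """Annual county estimates from a set of moving-window fits.

    Each fit contributes draws for the years inside its window; overlapping
    windows are combined per draw index by the unweighted window mean. Returns
    (estimates frame, combined DrawsCube).
    """
    if not fits:
        raise ValueError("at least one fit is required")
    spec0 = fits[0].spec
    for f in fits:
        if (f.spec.outcome, f.spec.sex) != (spec0.outcome, spec0.sex):
            raise ValueError("all fits must share outcome and sex")

    county_ids = list(counties.county_ids)
    years = sorted({y for f in fits for y in range(f.spec.window[0], f.spec.window[1] + 1)})
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(fits))

    per_window = {}
    for f, child in zip(fits, children):
        cube = simulate_uncertainty(
            f, counties, standard, n_draws=n_draws, seed=child, repair=repair
        )
        per_window[f.spec.window] = cube

    combined = np.empty((len(county_ids), len(years), n_draws))
    for j, y in enumerate(years):
        stacks = {
            w: cube.array[:, cube.years.index(y), :]
            for w, cube in per_window.items()
            if w[0] <= y <= w[1]
        }
        combined[:, j, :] = combine_windows(stacks, y)
    cube = DrawsCube(county_ids, years, combined)
    est = summarize_cube(cube, spec0.sex, spec0.outcome)
    return est, cube
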