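"""Race aggregation, age standardization, and simulated uncertainty."""

import numpy as np
import pandas as pd
import pytest

from countyprev import aggregation as agg
from countyprev import models as mdl
from countyprev import synthetic as syn
from countyprev.errors import SchemaError


class TestAggregateRace:
    def test_equal_weights(self):
        assert agg.aggregate_race({"white": 0.2, "black": 0.4}, {"white": 1, "black": 1}) == pytest.approx(0.3)

    def test_single_race_identity(self):
        assert agg.aggregate_race({"white": 0.37}, {"white": 123}) == pytest.approx(0.37)

    def test_unequal_weights(self):
        got = agg.aggregate_race({"white": 0.2, "black": 0.6}, {"white": 3, "black": 1})
        assert got == pytest.approx(0.3)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            agg.aggregate_race({"white": 0.2}, {"white": 0})

    def test_race_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            agg.aggregate_race({"white": 0.2}, {"white": 1, "black": 2})

    def test_convex_combination_bounds(self):
        p = {"white": 0.1, "black": 0.9, "other": 0.4}
        pop = {"white": 5, "black": 2, "other": 3}
        got = agg.aggregate_race(p, pop)
        assert min(p.values()) <= got <= max(p.values())


class TestAgeStandardize:
    def _standard(self, weights):
        return agg.StandardPopulation(weights)

    def test_uniform_prevalence_unchanged(self):
        std = self._standard({a: 1 / 6 for a in syn.AGE_GROUPS})
        assert agg.age_standardize({a: 0.25 for a in syn.AGE_GROUPS}, std) == pytest.approx(0.25)

    def test_two_group_example(self):
        std = self._standard({"20-34": 0.5, "75+": 0.5})
        assert agg.age_standardize({"20-34": 0.1, "75+": 0.3}, std) == pytest.approx(0.2)

    def test_relabeling_invariance(self):
        w = dict(zip(syn.AGE_GROUPS, (0.3, 0.25, 0.2, 0.1, 0.1, 0.05)))
        p = dict(zip(syn.AGE_GROUPS, (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)))
        perm = list(syn.AGE_GROUPS)[::-1]
        w2 = {a: w[a] for a in perm}
        p2 = {a: p[a] for a in perm}
        assert agg.age_standardize(p, self._standard(w)) == pytest.approx(
            agg.age_standardize(p2, self._standard(w2))
        )

    def test_missing_age_group_named(self):
        std = self._standard({a: 1 / 6 for a in syn.AGE_GROUPS})
        p = {a: 0.2 for a in syn.AGE_GROUPS if a != "55-64"}
        with pytest.raises(SchemaError, match="55-64"):
            agg.age_standardize(p, std)

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            agg.StandardPopulation({"20-34": 0.5, "75+": 0.6})
        with pytest.raises(ValueError):
            agg.StandardPopulation({"20-34": -0.5, "75+": 1.5})

    def test_us_2000_standard_loads(self):
        std = agg.us_standard_2000()
        assert set(std.weights) == set(syn.AGE_GROUPS)
        assert sum(std.weights.values()) == pytest.approx(1.0, abs=1e-12)
        # younger adults dominate the 2000 age structure
        assert std.weights["20-34"] > std.weights["75+"]


def _toy_fit(g, intercept=-1.0, intercept_var=0.0, sigma2_u=0.0):
    """Hand-built naive FitResult with known mean and covariance."""
    spec = mdl.ModelSpec("naive", "obesity", "female", (2001, 2005))
    columns = (
        ["intercept"]
        + [f"race[{r}]" for r in syn.RACES[1:]]
        + [f"age[{a}]" for a in syn.AGE_GROUPS[1:]]
        + ["year_c"]
    )
    p = len(columns)
    C = len(g.county_ids)
    beta = np.zeros(p)
    beta[0] = intercept
    cov = np.zeros((p + C, p + C))
    cov[0, 0] = intercept_var
    return mdl.FitResult(
        spec=spec,
        columns=columns,
        beta=beta,
        sigma2_u=sigma2_u,
        u=pd.Series(0.0, index=g.county_ids),
        u_var=pd.Series(0.0, index=g.county_ids),
        cov=cov,
        loglik=0.0,
        diagnostics={"method": "laplace"},
    )


@pytest.fixture(scope="module")
def unit_grid():
    return syn.make_county_grid(1, 1)


@pytest.fixture(scope="module")
def flat_standard():
    return agg.StandardPopulation({a: 1 / 6 for a in syn.AGE_GROUPS})


class TestSimulateUncertainty:
    def test_zero_covariance_collapses_interval(self, unit_grid, flat_standard):
        fit = _toy_fit(unit_grid, intercept=-0.5, intercept_var=0.0)
        cube = agg.simulate_uncertainty(fit, unit_grid, flat_standard, n_draws=200, seed=0)
        est = agg.summarize_cube(cube, "female", "obesity")
        assert np.allclose(est["lower"], est["mean"])
        assert np.allclose(est["upper"], est["mean"])
        assert np.allclose(est["mean"], 1.0 / (1.0 + np.exp(0.5)))

    def test_matches_logit_normal_quantiles(self, unit_grid, flat_standard):
        """Gaussian logit pushed through the inverse link: percentile interval
        must match the closed-form logit-normal quantiles."""
        mu, sd = -1.0, 0.3
        fit = _toy_fit(unit_grid, intercept=mu, intercept_var=sd**2)
        cube = agg.simulate_uncertainty(fit, unit_grid, flat_standard, n_draws=20000, seed=1)
        est = agg.summarize_cube(cube, "female", "obesity").iloc[0]
        lo = 1.0 / (1.0 + np.exp(-(mu - 1.959964 * sd)))
        hi = 1.0 / (1.0 + np.exp(-(mu + 1.959964 * sd)))
        assert est["lower"] == pytest.approx(lo, abs=0.005)
        assert est["upper"] == pytest.approx(hi, abs=0.005)

    def test_same_seed_identical(self, unit_grid, flat_standard):
        fit = _toy_fit(unit_grid, intercept=-1.0, intercept_var=0.2)
        a = agg.simulate_uncertainty(fit, unit_grid, flat_standard, n_draws=300, seed=5)
        b = agg.simulate_uncertainty(fit, unit_grid, flat_standard, n_draws=300, seed=5)
        assert np.array_equal(a.array, b.array)

    def test_interval_orders_and_bounds(self, derived_small, flat_standard):
        g, _, records = derived_small
        fit = mdl.fit_variant(records, g, mdl.ModelSpec("naive", "obesity", "female", (2001, 2005)))
        cube = agg.simulate_uncertainty(fit, g, flat_standard, n_draws=400, seed=2)
        est = agg.summarize_cube(cube, "female", "obesity")
        assert ((0 <= est["lower"]) & (est["lower"] <= est["mean"])).all()
        assert ((est["mean"] <= est["upper"]) & (est["upper"] <= 1)).all()

    def test_negative_covariance_repaired_or_raises(self, unit_grid, flat_standard):
        fit = _toy_fit(unit_grid, intercept=-1.0, intercept_var=0.1)
        fit.cov[0, 1] = fit.cov[1, 0] = 5.0  # breaks positive semidefiniteness
        with pytest.raises(np.linalg.LinAlgError):
            agg.simulate_uncertainty(fit, unit_grid, flat_standard, n_draws=10, seed=0, repair=False)
        cube = agg.simulate_uncertainty(fit, unit_grid, flat_standard, n_draws=10, seed=0, repair=True)
        assert np.isfinite(cube.array).all()


class TestEstimatePrevalence:
    def test_windows_average_per_draw(self, derived_small, flat_standard):
        g, _, records = derived_small
        # two overlapping windows over a 5-year span is not possible; use 4-year
        fits = [
            mdl.fit_variant(records, g, mdl.ModelSpec("naive", "obesity", "female", w))
            for w in mdl.sliding_windows(2001, 2005, 4)
        ]
        est, cube = agg.estimate_prevalence(fits, g, flat_standard, n_draws=100, seed=3)
        assert sorted(est["year"].unique()) == [2001, 2002, 2003, 2004, 2005]
        # overlap year draws are the mean of the two windows' draws
        single = [
            agg.simulate_uncertainty(f, g, flat_standard, n_draws=100, seed=s)
            for f, s in zip(fits, np.random.SeedSequence(3).spawn(2))
        ]
        overlap = 0.5 * (
            single[0].array[:, single[0].years.index(2003), :]
            + single[1].array[:, single[1].years.index(2003), :]
        )
        assert np.allclose(cube.at("c00_00", 2003), overlap[0])
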