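"""Mixed-logit fitting, geospatial two-stage, windows and prediction."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from countyprev import models as mdl
from countyprev import outcomes as oc
from countyprev import synthetic as syn
from countyprev.errors import CollinearityError, DataError

from conftest import make_records


def _zeroed_outcomes(**kw):
    base = syn.GenerativeParams().outcomes
    return {
        k: op.zeroed(
            sex_effects=op.sex_effects,
            age_effects=op.age_effects,
            race_effects=op.race_effects,
            time_slope=op.time_slope,
            **kw,
        )
        for k, op in base.items()
    }


class TestSlidingWindows:
    def test_study_period(self):
        w = mdl.sliding_windows(2001, 2011, 5)
        assert len(w) == 7
        assert w[0] == (2001, 2005) and w[-1] == (2007, 2011)

    def test_single_window(self):
        assert mdl.sliding_windows(2001, 2005, 5) == [(2001, 2005)]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mdl.sliding_windows(2001, 2003, 5)


class TestBuildDesign:
    def test_naive_column_count(self, derived_small):
        g, _, records = derived_small
        des = mdl.build_design(records, g, mdl.ModelSpec("naive", "obesity", "female", (2001, 2005)))
        # intercept + 4 race + 5 age + time
        assert len(des.columns) == 11

    def test_full_column_count(self, derived_small):
        g, _, records = derived_small
        geo = pd.Series(0.1, index=g.county_ids)
        des = mdl.build_design(
            records, g, mdl.ModelSpec("full", "obesity", "female", (2001, 2005)), geo_term=geo
        )
        # naive 11 + 6 obesity county covariates + 4 racial composition + geo
        assert len(des.columns) == 22
        assert des.columns[-1] == "geo"

    def test_pa_outcomes_drop_physician_rate(self, derived_small):
        g, _, records = derived_small
        des = mdl.build_design(
            records, g,
            mdl.ModelSpec("covariate", "any_pa", "female", (2001, 2005)),
        )
        assert "docs_per_100k" not in des.columns
        assert "pm25" in des.columns

    def test_missing_race_excluded(self, derived_small):
        g, _, records = derived_small
        records = records.copy()
        records.iloc[:10, records.columns.get_loc("race")] = np.nan
        spec = mdl.ModelSpec("naive", "obesity", "female", (2001, 2005))
        des = mdl.build_design(records, g, spec)
        n_lost = (records.iloc[:10]["sex"] == "female").sum()
        full = mdl.build_design(records.dropna(subset=["race"]), g, spec)
        assert des.n.sum() == full.n.sum()
        assert des.n_excluded["missing_demographics"] == n_lost

    def test_empty_after_filtering_rejected(self, derived_small):
        g, _, records = derived_small
        with pytest.raises(DataError):
            mdl.build_design(records, g, mdl.ModelSpec("naive", "obesity", "female", (2051, 2055)))


class TestNeighborMean:
    def test_examples(self, grid33):
        effects = pd.Series(0.0, index=grid33.county_ids)
        effects[["c00_01", "c01_00", "c01_02", "c02_01"]] = [0.2, 0.4, 0.6, 0.0]
        assert mdl.neighbor_mean(effects, grid33, "c01_01") == pytest.approx(0.3)
        effects[["c00_01", "c01_00", "c01_02", "c02_01"]] = [0.1, -0.1, 0.1, -0.1]
        assert mdl.neighbor_mean(effects, grid33, "c01_01") == pytest.approx(0.0)

    def test_isolated_county_defaults_to_zero(self):
        g = syn.make_county_grid(1, 1)
        assert mdl.neighbor_mean(pd.Series({"c00_00": 5.0}), g, "c00_00") == 0.0

    def test_unknown_county(self, grid33):
        with pytest.raises(KeyError):
            mdl.neighbor_mean(pd.Series(dtype=float), grid33, "nowhere")


class TestFitMixedLogit:
    def test_single_county_matches_plain_logistic(self):
        """With one county the variance hits zero and the fit is ordinary ML."""
        g = syn.make_county_grid(1, 1)
        truth = syn.simulate_truth(g, range(2001, 2006), syn.GenerativeParams(seed=3))
        rec = syn.simulate_survey(truth, g, 400, reporting_bias=syn.ReportingBias.none(), seed=4)
        d = oc.derive_outcomes(rec, None)
        spec = mdl.ModelSpec("naive", "obesity", "female", (2001, 2005))
        fit = mdl.fit_variant(d, g, spec)
        des = mdl.build_design(d, g, spec)
        glm = sm.GLM(
            np.column_stack([des.y, des.n - des.y]), des.X, family=sm.families.Binomial()
        ).fit(tol=1e-12)
        assert fit.sigma2_u == 0.0
        assert np.abs(fit.beta - glm.params).max() < 1e-6

    def test_zero_variance_data_recovers_slope(self):
        """sigma_u = 0 in truth: estimated variance collapses, slope within 3 SE."""
        g = syn.make_county_grid(4, 4)
        params = syn.GenerativeParams(seed=17, outcomes=_zeroed_outcomes(sd_u=0.0))
        truth = syn.simulate_truth(g, range(2001, 2006), params)
        rec = syn.simulate_survey(truth, g, 150, reporting_bias=syn.ReportingBias.none(), seed=18)
        d = oc.derive_outcomes(rec, None)
        fit = mdl.fit_variant(d, g, mdl.ModelSpec("naive", "obesity", "female", (2001, 2005)))
        assert fit.sigma2_u < 0.01
        i = fit.columns.index("year_c")
        se = np.sqrt(fit.cov[i, i])
        delta = truth.params.outcomes["obesity"].time_slope
        assert abs(fit.beta[i] - delta) < 3 * se

    def test_county_effect_recovery(self):
        """100 counties x ~500 obs: posterior means track the generating effects."""
        g = syn.make_county_grid(10, 10)
        params = syn.GenerativeParams(seed=23, outcomes=_zeroed_outcomes(sd_u=0.5, rho=0.0))
        truth = syn.simulate_truth(g, range(2001, 2006), params)
        rec = syn.simulate_survey(truth, g, 200, reporting_bias=syn.ReportingBias.none(), seed=24)
        d = oc.derive_outcomes(rec, None)
        fit = mdl.fit_variant(d, g, mdl.ModelSpec("naive", "obesity", "female", (2001, 2005)))
        u_true = truth.u["obesity"].reindex(g.county_ids)
        u_hat = fit.u_for(g.county_ids)
        assert np.corrcoef(u_hat, u_true)[0, 1] > 0.8

    def test_constant_county_covariates_diagnosed(self, derived_small):
        g, _, records = derived_small
        g2 = syn.CountyTable(
            g.county_ids,
            g.neighbors,
            g.covariates.copy(),
            g.race_populations.copy(),
        )
        g2.covariates.loc[:, :] = 0.5  # constant: collinear with the intercept
        spec = mdl.ModelSpec("covariate", "obesity", "female", (2001, 2005))
        with pytest.raises(CollinearityError):
            mdl.fit_variant(records, g2, spec)

    def test_matches_glmer_reference(self, tmp_path):
        """Independent oracle: lme4's Laplace GLMM on the same binomial cells."""
        g = syn.make_county_grid(5, 6)
        truth = syn.simulate_truth(g, range(2001, 2006), syn.GenerativeParams(seed=11))
        rec = syn.simulate_survey(truth, g, 60, seed=12)
        d = oc.derive_outcomes(rec, None)
        spec = mdl.ModelSpec("naive", "obesity", "female", (2001, 2005))
        fit = mdl.fit_variant(d, g, spec)
        des = mdl.build_design(d, g, spec)
        df = pd.DataFrame(des.X, columns=des.columns)
        df["y"] = des.y
        df["n"] = des.n
        df["county"] = [des.county_ids[i] for i in des.county_index]
        df.to_csv(tmp_path / "cells.csv", index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{tmp_path / "cells.csv"}", check.names=FALSE)\n'
            'preds <- setdiff(colnames(d), c("intercept","y","n","county"))\n'
            'f <- as.formula(paste("cbind(y, n-y) ~",'
            ' paste(sprintf("`%s`", preds), collapse="+"), "+ (1|county)"))\n'
            'm <- glmer(f, data=d, family=binomial, nAGQ=1)\n'
            'cat(jsonlite::toJSON(list(fixef=as.list(fixef(m)),'
            ' sigma2=as.numeric(VarCorr(m)$county[1])), auto_unbox=TRUE))\n'
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        py = dict(zip(fit.columns, fit.beta))
        for name, value in ref["fixef"].items():
            key = "intercept" if name == "(Intercept)" else name.strip("`")
            assert abs(py[key] - value) < 0.03
        assert fit.sigma2_u == pytest.approx(ref["sigma2"], rel=0.15, abs=0.01)


class TestVariants:
    def test_degenerate_geo_term_equals_naive(self, derived_small):
        """An all-zero geospatial column must reproduce the naive fit."""
        g, _, records = derived_small
        naive_spec = mdl.ModelSpec("naive", "obesity", "female", (2001, 2005))
        geo_spec = mdl.ModelSpec("geospatial", "obesity", "female", (2001, 2005))
        naive = mdl.fit_variant(records, g, naive_spec)
        design = mdl.build_design(records, g, geo_spec, geo_term=pd.Series(0.0, index=g.county_ids))
        fit = mdl.fit_mixed_logit(design)
        assert fit.beta_series["geo"] == 0.0
        shared = [c for c in naive.columns]
        assert np.allclose(
            fit.beta_series[shared].to_numpy(), naive.beta_series[shared].to_numpy(), atol=1e-6
        )

    def test_two_stage_geo_term_is_neighbor_mean_of_base(self, derived_small):
        g, _, records = derived_small
        spec = mdl.ModelSpec("geospatial", "obesity", "female", (2001, 2005))
        fit = mdl.fit_variant(records, g, spec)
        base = mdl.fit_variant(records, g, mdl.ModelSpec("naive", "obesity", "female", (2001, 2005)))
        expected = mdl.neighbor_means(base.u_for(g.county_ids), g)
        pd.testing.assert_series_equal(fit.geo_term, expected, check_names=False)


class TestPrediction:
    def test_matches_direct_formula(self, derived_small):
        g, _, records = derived_small
        spec = mdl.ModelSpec("naive", "obesity", "female", (2001, 2005))
        fit = mdl.fit_variant(records, g, spec)
        b = fit.beta_series
        x = (
            b["intercept"]
            + b["race[black]"]
            + b["age[45-54]"]
            + b["year_c"] * (2004 - 2003)
        )
        expected = 1.0 / (1.0 + np.exp(-(x + fit.u["c01_02"])))
        got = mdl.predict_cell(fit, "c01_02", 2004, "45-54", "black", g)
        assert got == pytest.approx(expected, rel=1e-12)
        assert 0.0 < got < 1.0

    def test_increasing_in_county_effect(self, derived_small):
        g, _, records = derived_small
        fit = mdl.fit_variant(records, g, mdl.ModelSpec("naive", "obesity", "female", (2001, 2005)))
        before = mdl.predict_cell(fit, "c00_00", 2003, "20-34", "white", g)
        fit.u["c00_00"] += 1.0
        after = mdl.predict_cell(fit, "c00_00", 2003, "20-34", "white", g)
        assert after > before

    def test_unknown_levels_rejected(self, derived_small):
        g, _, records = derived_small
        fit = mdl.fit_variant(records, g, mdl.ModelSpec("naive", "obesity", "female", (2001, 2005)))
        with pytest.raises(KeyError):
            mdl.predict_cell(fit, "c00_00", 2003, "18-19", "white", g)
        with pytest.raises(KeyError):
            mdl.predict_cell(fit, "nowhere", 2003, "20-34", "white", g)


class TestCombineWindows:
    def test_identity_for_single_window(self):
        assert mdl.combine_windows({(2001, 2005): 0.3}, 2003) == 0.3

    def test_mean_of_covering_windows(self):
        preds = {(2002, 2006): 0.30, (2006, 2010): 0.34}
        assert mdl.combine_windows(preds, 2006) == pytest.approx(0.32)

    def test_counts_all_covering_windows(self):
        preds = {(y, y + 4): float(y) for y in range(2001, 2008)}
        # 2006 is inside 2002-2006 ... 2006-2010
        assert mdl.combine_windows(preds, 2006) == pytest.approx(np.mean([2002, 2003, 2004, 2005, 2006]))

    def test_uncovered_year_rejected(self):
        with pytest.raises(ValueError):
            mdl.combine_windows({(2001, 2005): 0.3}, 2010)
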