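"""Small-area mixed-effects logistic models with a two-stage geospatial term.

Four model variants are fit per outcome, sex and five-year moving window:

* ``naive`` — individual covariates only (race, age group), a linear time
  trend, and a Gaussian county random intercept;
* ``covariate`` — the naive model plus county-level covariates (poverty,
  unemployment, percent rural, education, PM2.5, and for obesity the doctors/
  dentists rate) and county racial composition;
* ``geospatial`` — the naive model plus a geospatial term: for each county,
  the arithmetic mean of the neighboring counties' posterior random-effect
  means from a first-stage naive fit;
* ``full`` — the covariate model plus a geospatial term computed from a
  first-stage covariate fit.

The geospatial term is computed exactly once (no iteration to a fixed point)
and enters the second-stage model as an ordinary fixed covariate.

Fitting maximises a Laplace approximation to the marginal likelihood of the
logistic random-intercept model. For fixed random-effect variance sigma^2 the
fixed effects and county modes are found by penalized Newton iteration on
binomial-aggregated cells; sigma is then profiled by a bounded scalar search
on the Laplace objective

    l(sigma) = l_data(beta, u) - u'u / (2 sigma^2) - (C/2) log sigma^2
               - 1/2 sum_c log(w_c + 1 / sigma^2),

where w_c is the county's accumulated Fisher weight. Posterior county means
and variances, and a joint Gaussian covariance over (beta, u) taken from the
inverse penalized Hessian, feed the downstream uncertainty simulation. When
the profile maximum is at the sigma -> 0 boundary the model collapses to
ordinary logistic maximum likelihood, which is returned exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .errors import (
    CollinearityError,
    ConvergenceError,
    DataError,
    DegenerateFitError,
    SchemaError,
    SeparationError,
)
from .outcomes import outcome_vector
from .synthetic import AGE_GROUPS, RACES, SEXES

__all__ = [
    "VARIANTS",
    "PA_COUNTY_COVARIATES",
    "OBESITY_COUNTY_COVARIATES",
    "ModelSpec",
    "DesignBundle",
    "FitResult",
    "build_design",
    "fit_mixed_logit",
    "fit_variant",
    "neighbor_mean",
    "neighbor_means",
    "sliding_windows",
    "predict_cell",
    "predict_cells",
    "predict_pooled",
    "combine_windows",
]

VARIANTS = ("naive", "covariate", "geospatial", "full")

PA_COUNTY_COVARIATES = ("poverty", "unemployment", "pct_rural", "pct_hs_diploma", "pm25")
#: obesity models take every physical-activity covariate plus the physician rate
OBESITY_COUNTY_COVARIATES = PA_COUNTY_COVARIATES + ("docs_per_100k",)

_REF_RACE = RACES[0]       # white
_REF_AGE = AGE_GROUPS[0]   # 20-34


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: variant, outcome, sex, window, and county covariates."""

    variant: str
    outcome: str
    sex: str
    window: tuple
    covariates: tuple = None  # None -> outcome-specific default

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        y0, y1 = self.window
        if y1 < y0:
            raise ValueError("window must be ascending")
        object.__setattr__(self, "window", (int(y0), int(y1)))
        if self.covariates is not None:
            object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def county_covariates(self):
        if self.variant in ("naive", "geospatial"):
            return ()
        if self.covariates is not None:
            return self.covariates
        if self.outcome == "obesity":
            return OBESITY_COUNTY_COVARIATES
        return PA_COUNTY_COVARIATES

    @property
    def has_geo_term(self):
        return self.variant in ("geospatial", "full")

    @property
    def has_race_composition(self):
        return self.variant in ("covariate", "full")

    @property
    def year_center(self):
        return (self.window[0] + self.window[1]) / 2.0

    @property
    def base_variant(self):
        """First-stage variant supplying the geospatial term, if any."""
        return {"geospatial": "naive", "full": "covariate"}.get(self.variant)


@dataclass
class DesignBundle:
    """Binomial-aggregated design for one model fit."""

    y: np.ndarray              # successes per cell
    n: np.ndarray              # trials per cell
    X: np.ndarray              # fixed-effect design matrix
    columns: list
    county_index: np.ndarray   # int position into county_ids per cell
    county_ids: list           # counties with data, fit order
    cells: pd.DataFrame        # county_id, year, age_group, race labels
    spec: ModelSpec
    geo_term: pd.Series = None
    n_records: int = 0
    n_excluded: dict = field(default_factory=dict)


def _cell_matrix(cells, counties, spec, geo_term, year_center):
    """Fixed-effect design matrix for labelled cells; shared by fit and predict."""
    cols, data = [], []

    cols.append("intercept")
    data.append(np.ones(len(cells)))
    for r in RACES[1:]:
        cols.append(f"race[{r}]")
        data.append((cells["race"] == r).to_numpy(dtype=float))
    for a in AGE_GROUPS[1:]:
        cols.append(f"age[{a}]")
        data.append((cells["age_group"] == a).to_numpy(dtype=float))
    cols.append("year_c")
    data.append(cells["year"].to_numpy(dtype=float) - year_center)

    for cov in spec.county_covariates:
        if counties.covariates.empty or cov not in counties.covariates.columns:
            raise SchemaError(f"county covariate missing from CountyTable", column=cov)
        vals = counties.covariate_lookup(cells["county_id"], cells["year"], cov)
        if np.isnan(vals).any():
            bad = cells.loc[np.isnan(vals), ["county_id", "year"]].iloc[0]
            raise SchemaError(
                f"no value for county covariate at ({bad['county_id']}, {bad['year']})",
                column=cov,
            )
        cols.append(cov)
        data.append(vals)

    if spec.has_race_composition:
        shares = counties.race_shares
        pos = pd.Index(shares.index).get_indexer(cells["county_id"])
        if (pos < 0).any():
            unknown = cells["county_id"].iloc[int(np.argmin(pos))]
            raise SchemaError("county missing from race populations", row=unknown)
        for r in RACES[1:]:
            cols.append(f"race_comp[{r}]")
            data.append(shares[r].to_numpy()[pos])

    if spec.has_geo_term:
        if geo_term is None:
            raise DataError("geospatial variant requires a geo_term")
        vals = geo_term.reindex(cells["county_id"]).fillna(0.0).to_numpy()
        cols.append("geo")
        data.append(vals)

    return np.column_stack(data), cols


def build_design(records, counties, spec, geo_term=None):
    """Filter, aggregate and encode records for one model fit.

    Records outside the spec's sex or window, or with missing age, race,
    county or outcome, are excluded (exclusion counts are kept on the
    bundle). Remaining records are aggregated to binomial cells by
    county x year x age group x race.
    """
    df = records
    n0 = len(df)
    excl = {}

    df = df[df["sex"] == spec.sex]
    excl["sex"] = n0 - len(df)
    y0, y1 = spec.window
    m = (df["year"] >= y0) & (df["year"] <= y1)
    excl["window"] = int((~m).sum())
    df = df[m]
    demog = df[["county_id", "age_group", "race"]].notna().all(axis=1)
    excl["missing_demographics"] = int((~demog).sum())
    df = df[demog]
    yvec = outcome_vector(df, spec.outcome)
    excl["missing_outcome"] = int(yvec.isna().sum())
    df = df[yvec.notna()]
    yvec = yvec[yvec.notna()]

    if df.empty:
        raise DataError(
            f"no usable records for {spec.outcome}/{spec.sex} in window {spec.window}"
        )

    grouped = (
        pd.DataFrame(
            {
                "county_id": df["county_id"].to_numpy(),
                "year": df["year"].to_numpy(),
                "age_group": df["age_group"].to_numpy(),
                "race": df["race"].to_numpy(),
                "y": yvec.to_numpy(),
            }
        )
        .groupby(["county_id", "year", "age_group", "race"], observed=True)["y"]
        .agg(y="sum", n="size")
        .reset_index()
    )
    bad_race = set(grouped["race"]) - set(RACES)
    if bad_race:
        raise SchemaError(f"unknown race level(s) {sorted(bad_race)}", column="race")
    bad_age = set(grouped["age_group"]) - set(AGE_GROUPS)
    if bad_age:
        raise SchemaError(f"unknown age level(s) {sorted(bad_age)}", column="age_group")

    county_ids = sorted(grouped["county_id"].unique())
    county_index = pd.Index(county_ids).get_indexer(grouped["county_id"])
    X, columns = _cell_matrix(grouped, counties, spec, geo_term, spec.year_center)
    return DesignBundle(
        y=grouped["y"].to_numpy(dtype=float),
        n=grouped["n"].to_numpy(dtype=float),
        X=X,
        columns=columns,
        county_index=county_index,
        county_ids=county_ids,
        cells=grouped[["county_id", "year", "age_group", "race"]],
        spec=spec,
        geo_term=geo_term,
        n_records=int(len(df)),
        n_excluded=excl,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted model: fixed effects, variance component, posterior effects.

    ``cov`` is the joint Gaussian covariance approximation over the stacked
    parameter vector [beta, u_(fit counties)] (inverse penalized Hessian at
    the optimum), used by the uncertainty simulation. Counties absent from the
    fit window receive posterior mean 0 with variance ``sigma2_u``.
    """

    spec: ModelSpec
    columns: list
    beta: np.ndarray
    sigma2_u: float
    u: pd.Series               # posterior means, fit counties
    u_var: pd.Series           # posterior variances, fit counties
    cov: np.ndarray            # joint over [beta, u]
    loglik: float
    diagnostics: dict
    geo_term: pd.Series = None

    @property
    def beta_series(self):
        return pd.Series(self.beta, index=self.columns)

    def u_for(self, county_ids):
        """Posterior county-effect means with the documented 0 default."""
        return self.u.reindex(county_ids).fillna(0.0)

    def u_var_for(self, county_ids):
        return self.u_var.reindex(county_ids).fillna(self.sigma2_u)


def _binom_ll(y, n, eta):
    return float(y @ eta - n @ np.logaddexp(0.0, eta))


def _penalized_newton(y, n, X, ci, C, sigma2, theta0, max_iter=100, tol=1e-10):
    """Newton maximisation of the penalized binomial log likelihood.

    Returns (theta, penalized ll, eta, w, converged, iterations, trace).
    """
    p = X.shape[1]
    theta = theta0.copy()

    def evaluate(th):
        eta = X @ th[:p]
        if C:
            eta = eta + th[p:][ci]
        f = _binom_ll(y, n, eta)
        if C and sigma2 > 0:
            f -= float(th[p:] @ th[p:]) / (2.0 * sigma2)
        return f, eta

    f, eta = evaluate(theta)
    trace = [f]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = n * mu * (1.0 - mu) + 1e-12
        r = y - n * mu
        g = np.empty(p + C)
        g[:p] = X.T @ r
        Xw = X * w[:, None]
        H = np.empty((p + C, p + C))
        H[:p, :p] = X.T @ Xw
        if C:
            g[p:] = np.bincount(ci, weights=r, minlength=C) - theta[p:] / sigma2
            Hub = np.zeros((C, p))
            np.add.at(Hub, ci, Xw)
            H[p:, :p] = Hub
            H[:p, p:] = Hub.T
            wc = np.bincount(ci, weights=w, minlength=C)
            H[p:, p:] = np.diag(wc + 1.0 / sigma2)
        H[np.diag_indices_from(H)] += 1e-10
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]

        t, f_new, eta_new = 1.0, -np.inf, eta
        theta_new = theta
        for _ in range(40):
            cand = theta + t * step
            f_new, eta_new = evaluate(cand)
            if f_new >= f - 1e-13:
                theta_new = cand
                break
            t *= 0.5
        improvement = f_new - f
        theta, f, eta = theta_new, f_new, eta_new
        trace.append(f)
        if np.abs(g).max() < tol * (1.0 + abs(f)) or (0.0 <= improvement < tol * (1.0 + abs(f))):
            converged = True
            break
    return theta, f, eta, converged, it, trace


def _check_rank(X, columns):
    _, R, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (d[0] if d.size else 0.0)
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        dropped = [columns[j] for j in piv[rank:]]
        raise CollinearityError(dropped)


def fit_mixed_logit(
    design,
    max_iter=200,
    tol=1e-8,
    sigma_bounds=(1e-3, 5.0),
    stage=None,
):
    """Fit the logistic random-intercept model on a design bundle.

    The Laplace-approximate marginal likelihood is profiled over the
    random-effect SD by a bounded scalar search; when the profile maximum sits
    at the lower boundary (including the single-county case) the model
    collapses to ordinary logistic maximum likelihood and the fixed effects
    are those of the unpenalized Newton fit.
    """
    y, n, X, ci = design.y, design.n, design.X, design.county_index
    C, p = len(design.county_ids), X.shape[1]
    if y.sum() == 0 or y.sum() == n.sum():
        raise DegenerateFitError("outcome is constant; logistic fit undefined")

    # an identically-zero column (e.g. a degenerate geospatial term from an
    # all-zero first stage) carries no information: fit without it and report
    # its coefficient as exactly 0. Constant non-zero columns still raise.
    zero = ~X.any(axis=0)
    if zero.any():
        from dataclasses import replace as _dc_replace

        keep = ~zero
        reduced = _dc_replace(
            design,
            X=X[:, keep],
            columns=[c for c, k in zip(design.columns, keep) if k],
        )
        sub = fit_mixed_logit(reduced, max_iter=max_iter, tol=tol,
                              sigma_bounds=sigma_bounds, stage=stage)
        beta = np.zeros(p)
        beta[keep] = sub.beta
        cov = np.zeros((p + C, p + C))
        idx = np.concatenate([np.flatnonzero(keep), np.arange(p, p + C)])
        cov[np.ix_(idx, idx)] = sub.cov
        sub.diagnostics["zero_columns"] = [c for c, z in zip(design.columns, zero) if z]
        return FitResult(
            spec=design.spec, columns=list(design.columns), beta=beta,
            sigma2_u=sub.sigma2_u, u=sub.u, u_var=sub.u_var, cov=cov,
            loglik=sub.loglik, diagnostics=sub.diagnostics, geo_term=design.geo_term,
        )

    _check_rank(X, design.columns)

    warm = {"theta": np.zeros(p + C)}
    outer_evals = []

    def negative_marginal(log_s):
        sigma2 = float(np.exp(2.0 * log_s))
        theta, fpen, eta, conv, its, _ = _penalized_newton(
            y, n, X, ci, C, sigma2, warm["theta"], max_iter=max_iter, tol=1e-9
        )
        warm["theta"] = theta
        mu = expit(eta)
        w = n * mu * (1.0 - mu)
        wc = np.bincount(ci, weights=w, minlength=C)
        ll = fpen - 0.5 * C * np.log(sigma2) - 0.5 * np.log(wc + 1.0 / sigma2).sum()
        outer_evals.append((sigma2, ll, conv, its))
        return -ll

    lo, hi = np.log(sigma_bounds[0]), np.log(sigma_bounds[1])
    res = minimize_scalar(
        negative_marginal, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
    )
    ll_mixed = -float(res.fun)

    # sigma -> 0 limit: ordinary logistic maximum likelihood
    theta_plain, ll_plain, eta_plain, conv_plain, its_plain, trace_plain = _penalized_newton(
        y, n, X, np.zeros(0, dtype=int), 0, 0.0, np.zeros(p), max_iter=max_iter, tol=1e-12
    )
    if not conv_plain:
        # diverging linear predictors with a still-improving likelihood are the
        # signature of (quasi-)complete separation
        if np.abs(eta_plain).max() > 30.0:
            raise SeparationError(
                "complete or quasi-complete separation diagnosed (diverging linear predictor)",
                trace=trace_plain,
                stage=stage,
            )
        if C == 0:
            raise ConvergenceError(
                f"logistic fit did not converge in {max_iter} iterations",
                trace=trace_plain,
                stage=stage,
            )

    at_boundary = res.x <= lo + 5e-4 or ll_plain >= ll_mixed - 1e-7
    if at_boundary:
        mu = expit(eta_plain)
        w = n * mu * (1.0 - mu) + 1e-12
        Hbb = X.T @ (X * w[:, None])
        cov = np.zeros((p + C, p + C))
        cov[:p, :p] = np.linalg.inv(Hbb)
        return FitResult(
            spec=design.spec,
            columns=list(design.columns),
            beta=theta_plain[:p],
            sigma2_u=0.0,
            u=pd.Series(0.0, index=design.county_ids),
            u_var=pd.Series(0.0, index=design.county_ids),
            cov=cov,
            loglik=ll_plain,
            diagnostics={
                "method": "laplace",
                "boundary_sigma_zero": True,
                "iterations": its_plain,
                "outer_evaluations": len(outer_evals),
                "converged": True,
                "stage": stage,
                "n_cells": int(len(y)),
                "n_counties": C,
            },
            geo_term=design.geo_term,
        )

    sigma2 = float(np.exp(2.0 * res.x))
    theta, fpen, eta, conv, its, trace = _penalized_newton(
        y, n, X, ci, C, sigma2, warm["theta"], max_iter=max_iter, tol=1e-12
    )
    if not conv:
        raise ConvergenceError(
            f"penalized Newton did not converge in {max_iter} iterations at sigma^2={sigma2:.4g}",
            trace=trace,
            stage=stage,
        )
    mu = expit(eta)
    w = n * mu * (1.0 - mu) + 1e-12
    Xw = X * w[:, None]
    H = np.empty((p + C, p + C))
    H[:p, :p] = X.T @ Xw
    Hub = np.zeros((C, p))
    np.add.at(Hub, ci, Xw)
    H[p:, :p] = Hub
    H[:p, p:] = Hub.T
    wc = np.bincount(ci, weights=w, minlength=C)
    H[p:, p:] = np.diag(wc + 1.0 / sigma2)
    H[np.diag_indices_from(H)] += 1e-10
    cov = np.linalg.inv(H)
    cov = 0.5 * (cov + cov.T)

    return FitResult(
        spec=design.spec,
        columns=list(design.columns),
        beta=theta[:p],
        sigma2_u=sigma2,
        u=pd.Series(theta[p:], index=design.county_ids),
        u_var=pd.Series(np.diag(cov)[p:], index=design.county_ids),
        cov=cov,
        loglik=ll_mixed,
        diagnostics={
            "method": "laplace",
            "boundary_sigma_zero": False,
            "iterations": its,
            "outer_evaluations": len(outer_evals),
            "converged": True,
            "stage": stage,
            "n_cells": int(len(y)),
            "n_counties": C,
        },
        geo_term=design.geo_term,
    )


# ---------------------------------------------------------------------------
# Geospatial term and variants
# ---------------------------------------------------------------------------


def neighbor_mean(effects, counties, county_id):
    """Arithmetic mean of neighboring counties' effects; 0 when isolated.

    ``effects`` may omit counties; omitted neighbors contribute the
    documented default of 0.
    """
    if county_id not in counties.neighbors:
        raise KeyError(f"unknown county {county_id!r}")
    nbrs = counties.neighbors[county_id]
    if not nbrs:
        return 0.0
    eff = pd.Series(effects) if not isinstance(effects, pd.Series) else effects
    return float(eff.reindex(sorted(nbrs)).fillna(0.0).mean())


def neighbor_means(effects, counties):
    """Vectorised :func:`neighbor_mean` over every county in the table."""
    return pd.Series(
        {c: neighbor_mean(effects, counties, c) for c in counties.county_ids},
        name="geo",
    )


def fit_variant(records, counties, spec, **fit_kwargs):
    """Fit one model variant, running the two-stage geospatial scheme if needed.

    ``geospatial`` fits the naive model first; ``full`` fits the covariate
    model first. The first-stage posterior county means are averaged over each
    county's neighbors and the result enters the second stage as a fixed
    covariate; the second stage is run exactly once.
    """
    if spec.base_variant is None:
        design = build_design(records, counties, spec)
        return fit_mixed_logit(design, stage="base", **fit_kwargs)
    base_spec = replace(spec, variant=spec.base_variant)
    base = fit_variant(records, counties, base_spec, **fit_kwargs)
    geo = neighbor_means(base.u_for(counties.county_ids), counties)
    design = build_design(records, counties, spec, geo_term=geo)
    return fit_mixed_logit(design, stage="geo-augmented", **fit_kwargs)


def sliding_windows(first_year, last_year, width=5):
    """All consecutive year spans of the given width, ascending."""
    if width < 1:
        raise ValueError("width must be positive")
    if last_year - first_year + 1 < width:
        raise ValueError(
            f"range {first_year}-{last_year} shorter than window width {width}"
        )
    return [(y, y + width - 1) for y in range(first_year, last_year - width + 2)]


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_cells(fit, counties, cells):
    """Predicted probability for each labelled cell (county, year, age, race)."""
    X, _ = _cell_matrix(cells, counties, fit.spec, fit.geo_term, fit.spec.year_center)
    u = fit.u_for(counties.county_ids)
    pos = pd.Index(counties.county_ids).get_indexer(cells["county_id"])
    if (pos < 0).any():
        unknown = cells["county_id"].iloc[int(np.argmin(pos))]
        raise KeyError(f"unknown county {unknown!r}")
    eta = X @ fit.beta + u.to_numpy()[pos]
    return expit(eta)


def predict_cell(fit, county_id, year, age_group, race, counties):
    """Single-cell prediction; strictly inside (0, 1)."""
    if age_group not in AGE_GROUPS:
        raise KeyError(f"unknown age group {age_group!r}")
    if race not in RACES:
        raise KeyError(f"unknown race {race!r}")
    cells = pd.DataFrame(
        [{"county_id": county_id, "year": year, "age_group": age_group, "race": race}]
    )
    return float(predict_cells(fit, counties, cells)[0])


def predict_pooled(fit, counties, cells, weights):
    """Weighted mean predicted probability over labelled cells."""
    p = predict_cells(fit, counties, cells)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    return float(np.average(p, weights=w))


def combine_windows(window_predictions, year):
    """Annual value as the unweighted mean over windows covering the year.

    ``window_predictions`` maps (start, end) -> value (scalar or array).
    """
    covering = [v for (y0, y1), v in window_predictions.items() if y0 <= year <= y1]
    if not covering:
        raise ValueError(f"year {year} is covered by no window")
    return np.mean(covering, axis=0) if np.ndim(covering[0]) else float(np.mean(covering))
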