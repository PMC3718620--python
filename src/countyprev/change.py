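"""Percentage-point changes over time and the ecological change regression.

Changes between two calendar years are computed on the percent scale; when
draw sets are supplied (index-aligned, from the same simulation stream) the
change interval is the percentile interval of the draw-wise differences, so
the between-year correlation of the estimates is propagated.

The ecological regression relates county-level change in obesity prevalence
to change in sufficient-activity prevalence, controlling for percent rural,
changes in poverty, unemployment and the doctors-per-100k rate, and the
baseline obesity level — an area-level association, not an individual-level
causal claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError

__all__ = [
    "ChangeRecord",
    "EcoRegressionResult",
    "pp_change",
    "changes_table",
    "build_change_covariates",
    "ecological_regression",
    "ECO_REGRESSORS",
]

ECO_REGRESSORS = (
    "change_pa",
    "pct_rural",
    "change_poverty",
    "change_unemployment",
    "change_docs_per_100k",
    "baseline_obesity",
)


@dataclass
class ChangeRecord:
    """A county's percentage-point change with an optional simulated interval."""

    pp_change: float
    lower: float = None
    upper: float = None
    baseline: float = None

    def __post_init__(self):
        if self.lower is not None and not (self.lower <= self.pp_change <= self.upper):
            raise ValueError("interval must bracket the point change")


def pp_change(est_start, est_end, draws_start=None, draws_end=None):
    """Percentage-point change end - start (both on the percent scale).

    With index-aligned draw vectors the 95% interval is the 2.5/97.5
    percentile of the draw-wise differences.
    """
    point = float(est_end) - float(est_start)
    lower = upper = None
    if (draws_start is None) != (draws_end is None):
        raise ValueError("supply both draw vectors or neither")
    if draws_start is not None:
        a = np.asarray(draws_start, dtype=float)
        b = np.asarray(draws_end, dtype=float)
        if a.shape != b.shape:
            raise ValueError("draw vectors must be index-aligned with equal length")
        diff = b - a
        lower = float(np.percentile(diff, 2.5))
        upper = float(np.percentile(diff, 97.5))
        # the simulated interval brackets the simulated mean change; anchor the
        # point change inside it to keep the record self-consistent
        lower = min(lower, point)
        upper = max(upper, point)
    return ChangeRecord(point, lower, upper, baseline=float(est_start))


def changes_table(cube, year_start=2001, year_end=2009):
    """Per-county percentage-point changes from a prevalence draws cube.

    The cube holds probabilities; output is on the percent scale.
    """
    rows = []
    for c in cube.county_ids:
        d0 = cube.at(c, year_start) * 100.0
        d1 = cube.at(c, year_end) * 100.0
        rec = pp_change(d0.mean(), d1.mean(), d0, d1)
        rows.append(
            {
                "county_id": c,
                "baseline": rec.baseline,
                "pp_change": rec.pp_change,
                "lower": rec.lower,
                "upper": rec.upper,
            }
        )
    return pd.DataFrame(rows)


def build_change_covariates(counties, year_start=2001, year_end=2009):
    """County covariate levels/changes used by the ecological regression."""
    cov = counties.covariates
    start = cov.xs(year_start, level="year")
    end = cov.xs(year_end, level="year")
    return pd.DataFrame(
        {
            "county_id": start.index,
            "pct_rural": end["pct_rural"].to_numpy() * 100.0,
            "change_poverty": (end["poverty"] - start["poverty"]).to_numpy() * 100.0,
            "change_unemployment": (end["unemployment"] - start["unemployment"]).to_numpy() * 100.0,
            "change_docs_per_100k": (end["docs_per_100k"] - start["docs_per_100k"]).to_numpy(),
        }
    )


@dataclass
class EcoRegressionResult:
    """OLS coefficients and conventional standard errors, one row per term."""

    params: pd.DataFrame  # index: term; columns: coefficient, se
    n: int
    r_squared: float

    def coefficient(self, term):
        return float(self.params.loc[term, "coefficient"])


def ecological_regression(changes, response="change_obesity", regressors=ECO_REGRESSORS):
    """OLS of change in obesity on change in activity and county controls.

    ``changes`` must contain the response and every regressor as columns;
    only complete cases are used. Rank deficiency raises a collinearity
    error naming the offending columns.
    """
    regressors = list(regressors)
    df = changes[[response, *regressors]].dropna()
    if len(df) <= len(regressors) + 1:
        raise ValueError(
            f"need more counties ({len(df)}) than regression terms ({len(regressors) + 1})"
        )
    X = df[regressors].to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(df)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # locate dependent columns via pivoted QR on the full design
        from scipy.linalg import qr

        _, R, piv = qr(Xc, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        tol = max(Xc.shape) * np.finfo(float).eps * d[0]
        names = ["intercept", *regressors]
        raise CollinearityError([names[j] for j in piv[(d <= tol).nonzero()[0]]] or
                                [names[j] for j in piv[rank:]])
    res = sm.OLS(df[response].to_numpy(dtype=float), sm.add_constant(X)).fit()
    params = pd.DataFrame(
        {
            "coefficient": res.params,
            "se": res.bse,
        },
        index=pd.Index(["intercept", *regressors], name="term"),
    )
    return EcoRegressionResult(params=params, n=int(res.nobs), r_squared=float(res.rsquared))
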