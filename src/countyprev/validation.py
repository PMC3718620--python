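"""Model selection by down-sampling against gold-standard counties.

Counties with many pooled records (at least 900 by default over 2001-2005)
serve as their own gold standard: the direct pooled survey proportion. Those
counties are repeatedly sampled down to 10, 50 and 100 individuals, all four
model variants are refit on the reduced data (all other counties keep their
full data), and the model-based county estimates are scored against the gold
standard with Lin's concordance correlation coefficient, mean relative error
and root mean squared error. The variant with the best average concordance
wins and is used for reporting.

Down-sampling is nested-deterministic: the subset drawn for a given
(master seed, replicate, county, m) is always the same, so the whole metric
grid reproduces bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationInfeasibleError
from .models import ModelSpec, VARIANTS, fit_variant, predict_cells
from .outcomes import outcome_vector
from .synthetic import SEXES

__all__ = [
    "ValidationReport",
    "select_gold_counties",
    "gold_standard",
    "downsample",
    "lin_ccc",
    "mean_relative_error",
    "rmse",
    "run_validation",
    "select_model",
]

GOLD_SPAN = (2001, 2005)
DOWNSAMPLE_SIZES = (10, 50, 100)


# ---------------------------------------------------------------------------
# Gold standard and down-sampling
# ---------------------------------------------------------------------------


def _usable(records, outcome):
    """Records usable for an outcome: demographics and the outcome non-missing."""
    ok = records[["county_id", "sex", "age_group", "race"]].notna().all(axis=1)
    ok &= outcome_vector(records, outcome).notna()
    return records[ok]


def select_gold_counties(records, outcome, min_n=900, span=GOLD_SPAN):
    """Counties with at least ``min_n`` usable records within the span."""
    sub = _usable(records, outcome)
    sub = sub[(sub["year"] >= span[0]) & (sub["year"] <= span[1])]
    counts = sub.groupby("county_id").size()
    gold = sorted(counts[counts >= min_n].index)
    if not gold:
        raise ValidationInfeasibleError(
            f"no county has >= {min_n} usable records in {span[0]}-{span[1]}"
        )
    return gold


def gold_standard(records, county_id, outcome, span=GOLD_SPAN, sex=None):
    """Direct pooled proportion of the outcome for one county over the span."""
    sub = _usable(records, outcome)
    sub = sub[
        (sub["county_id"] == county_id)
        & (sub["year"] >= span[0])
        & (sub["year"] <= span[1])
    ]
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    if sub.empty:
        raise ValueError(f"no usable records for county {county_id!r}")
    return float(outcome_vector(sub, outcome).mean())


def _county_key(county_id):
    return zlib.crc32(str(county_id).encode()) & 0x7FFFFFFF


def downsample(records, county_id, m, replicate, seed):
    """Simple random sample without replacement of ``m`` of a county's records.

    Deterministic per (seed, replicate, county, m) via an independent spawned
    bit-generator stream.
    """
    sub = records[records["county_id"] == county_id]
    if m > len(sub):
        raise ValueError(
            f"cannot sample {m} records from county {county_id!r} with {len(sub)}"
        )
    ss = np.random.SeedSequence(seed, spawn_key=(int(m), int(replicate), _county_key(county_id)))
    rng = np.random.default_rng(ss)
    idx = rng.choice(len(sub), size=m, replace=False)
    return sub.iloc[np.sort(idx)]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def lin_ccc(x, y):
    """Lin's concordance correlation coefficient (population moments).

    ccc = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2); 1 means
    perfect agreement with the identity line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 2:
        raise UndefinedMetricError("CCC needs at least two pairs")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise UndefinedMetricError("CCC undefined: both vectors are constant")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def mean_relative_error(x, y, absolute=False):
    """Signed mean of (x - y) / y; set ``absolute`` for the magnitude version."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if (y == 0).any():
        bad = np.nonzero(y == 0)[0]
        raise UndefinedMetricError(f"relative error undefined at zero gold value(s), index {bad.tolist()}")
    rel = (x - y) / y
    return float(np.abs(rel).mean() if absolute else rel.mean())


def rmse(x, y):
    """Root mean squared error of x against y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return float(np.sqrt(np.mean((x - y) ** 2)))


# ---------------------------------------------------------------------------
# The experiment
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Metric grid, per-(variant, m) summary, and the winning variant."""

    grid: pd.DataFrame          # variant, m, replicate, ccc, mre, rmse, failed
    summary: pd.DataFrame       # variant, m, mean ccc/mre/rmse over replicates
    selected_variant: str
    gold_counties: list = field(default_factory=list)
    outcome: str = ""
    sexes: tuple = ()


def _pooled_model_estimate(fit, counties, comp_cells):
    """Model-based pooled prevalence for one county over its full composition."""
    p = predict_cells(fit, counties, comp_cells)
    return float(np.average(p, weights=comp_cells["count"].to_numpy(dtype=float)))


def run_validation(
    records,
    counties,
    outcome,
    sexes=SEXES,
    reps=25,
    seed=0,
    m_list=DOWNSAMPLE_SIZES,
    min_n=900,
    span=GOLD_SPAN,
    variants=VARIANTS,
):
    """Down-sampling validation of all model variants for one outcome.

    For each sample size m and replicate, gold counties' records are replaced
    by an m-record random subset (non-gold counties keep full data), each
    variant is refit per sex on the reduced data, and the pooled model
    estimate for every (gold county, sex) — the prediction averaged over the
    county's full record composition — is scored against the direct gold
    proportion. Fit failures mark the replicate as failed rather than
    aborting the experiment.
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    sexes = tuple(sexes)
    base = _usable(records, outcome)
    base = base[base["sex"].isin(sexes)]
    gold = select_gold_counties(base, outcome, min_n=min_n, span=span)
    in_span = base[(base["year"] >= span[0]) & (base["year"] <= span[1])]

    gold_values = {
        (c, s): gold_standard(base, c, outcome, span=span, sex=s)
        for c in gold
        for s in sexes
    }
    # full-data composition cells per (county, sex), used to pool predictions
    comp = {}
    for (c, s) in gold_values:
        sub = in_span[(in_span["county_id"] == c) & (in_span["sex"] == s)]
        cells = (
            sub.groupby(["county_id", "year", "age_group", "race"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        comp[(c, s)] = cells

    non_gold = in_span[~in_span["county_id"].isin(gold)]
    gold_frames = {c: in_span[in_span["county_id"] == c] for c in gold}

    rows = []
    for m in m_list:
        for rep in range(reps):
            sampled = [downsample(gold_frames[c], c, m, rep, seed) for c in gold]
            data = pd.concat([non_gold, *sampled], ignore_index=True)
            for variant in variants:
                try:
                    ests, golds = [], []
                    fits = {
                        s: fit_variant(
                            data, counties, ModelSpec(variant, outcome, s, span)
                        )
                        for s in sexes
                    }
                    for (c, s), g in gold_values.items():
                        ests.append(_pooled_model_estimate(fits[s], counties, comp[(c, s)]))
                        golds.append(g)
                    rows.append(
                        {
                            "variant": variant,
                            "m": m,
                            "replicate": rep,
                            "ccc": lin_ccc(ests, golds),
                            "mre": mean_relative_error(ests, golds),
                            "rmse": rmse(ests, golds),
                            "failed": False,
                        }
                    )
                except Exception as exc:  # fit failures are recorded, not fatal
                    rows.append(
                        {
                            "variant": variant,
                            "m": m,
                            "replicate": rep,
                            "ccc": np.nan,
                            "mre": np.nan,
                            "rmse": np.nan,
                            "failed": True,
                            "error": f"{type(exc).__name__}: {exc}",
                        }
                    )
    grid = pd.DataFrame(rows)
    summary = (
        grid[~grid["failed"]]
        .groupby(["variant", "m"], observed=True)[["ccc", "mre", "rmse"]]
        .mean()
        .reset_index()
    )
    report = ValidationReport(
        grid=grid,
        summary=summary,
        selected_variant="",
        gold_counties=gold,
        outcome=outcome,
        sexes=sexes,
    )
    report.selected_variant = select_model(report)
    return report


def select_model(report):
    """Winning variant: highest mean CCC across sample sizes.

    Exact ties are broken by lower mean RMSE, then lower mean |MRE|.
    """
    summary = report.summary
    if summary.empty:
        raise ValueError("validation report contains no successful replicates")
    expected = {(v, m) for v in report.grid["variant"].unique() for m in report.grid["m"].unique()}
    have = set(zip(summary["variant"], summary["m"]))
    missing = expected - have
    if missing:
        raise ValueError(f"incomplete validation report; missing cells: {sorted(missing)}")
    agg = summary.groupby("variant")[["ccc", "mre", "rmse"]].mean()
    ranked = agg.assign(abs_mre=agg["mre"].abs()).sort_values(
        by=["ccc", "rmse", "abs_mre"], ascending=[False, True, True]
    )
    return str(ranked.index[0])
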