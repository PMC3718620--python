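"""Regression calibration of self-reported BMI against examination data.

Self-reported height and weight understate BMI in a systematic way. The
correction follows the standard two-survey design: for every two-year
examination cycle, mean BMI is computed by sex and age group from the
self-report survey (reported) and from the examination survey (measured);
measured cell means are then regressed on reported cell means separately for
males and females, and the fitted line converts each individual's reported
BMI into a corrected BMI. Obesity is classified from the corrected value at
the conventional threshold of 30 kg/m^2 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateFitError
from .synthetic import AGE_GROUPS, SEXES

__all__ = [
    "OBESITY_BMI_THRESHOLD",
    "CalibrationModel",
    "compute_bmi",
    "cell_means",
    "reported_cells",
    "fit_calibration",
    "apply_calibration",
    "classify_obese",
]

OBESITY_BMI_THRESHOLD = 30.0


def compute_bmi(weight, height):
    """BMI in kg/m^2 from weight (kg) and height (m).

    Scalar or array; raises on non-positive inputs (NaN passes through as
    missing).
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(w[~np.isnan(w)] <= 0) or np.any(h[~np.isnan(h)] <= 0):
        raise ValueError("weight and height must be positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def reported_bmi(records):
    """Per-record BMI from reported weight/height; NaN where either is missing."""
    w = pd.to_numeric(records["reported_weight"], errors="coerce")
    h = pd.to_numeric(records["reported_height"], errors="coerce")
    valid = w.notna() & h.notna()
    if ((w[valid] <= 0) | (h[valid] <= 0)).any():
        raise ValueError("reported weight and height must be positive where present")
    bmi = pd.Series(np.nan, index=records.index, dtype=float)
    bmi[valid] = w[valid] / h[valid] ** 2
    return bmi


def cell_means(records, cycle):
    """Mean reported BMI by (sex, age group) within one two-year cycle.

    Returns a frame with columns sex, age_group, mean_bmi, n. Records with
    missing anthropometrics are excluded; a cycle with no usable records
    yields an empty frame (not an error).
    """
    y0, y1 = cycle
    sub = records[(records["year"] >= y0) & (records["year"] <= y1)].copy()
    if sub.empty:
        return pd.DataFrame(columns=["sex", "age_group", "mean_bmi", "n"])
    sub["bmi"] = reported_bmi(sub)
    sub = sub.dropna(subset=["bmi", "sex", "age_group"])
    if sub.empty:
        return pd.DataFrame(columns=["sex", "age_group", "mean_bmi", "n"])
    g = (
        sub.groupby(["sex", "age_group"], observed=True)["bmi"]
        .agg(mean_bmi="mean", n="size")
        .reset_index()
    )
    return g


def reported_cells(records, cycles):
    """Stack :func:`cell_means` over cycles, tagging each row with its cycle."""
    frames = []
    for (y0, y1) in cycles:
        cm = cell_means(records, (y0, y1))
        if not cm.empty:
            cm = cm.assign(cycle_start=y0, cycle_end=y1)
            frames.append(cm)
    if not frames:
        return pd.DataFrame(columns=["sex", "age_group", "mean_bmi", "n", "cycle_start", "cycle_end"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class CalibrationModel:
    """Per-sex linear map from reported to corrected BMI.

    ``coefficients`` maps sex to (intercept, slope); ``provenance`` records
    the matched cells each fit used.
    """

    coefficients: dict
    provenance: dict = field(default_factory=dict)

    def correct(self, sex, bmi):
        a, b = self.coefficients[sex]
        return a + b * np.asarray(bmi, dtype=float)

    def to_dict(self):
        return {
            sex: {"intercept": float(a), "slope": float(b)}
            for sex, (a, b) in self.coefficients.items()
        }

    @classmethod
    def from_dict(cls, d):
        return cls({sex: (v["intercept"], v["slope"]) for sex, v in d.items()})


_CELL_KEYS = ["cycle_start", "cycle_end", "sex", "age_group"]


def fit_calibration(reported, measured, weight_by_n=False):
    """OLS of measured on reported cell means, separately per sex.

    ``reported`` and ``measured`` are cell frames with columns
    (cycle_start, cycle_end, sex, age_group, mean_bmi[, n]); cells are matched
    exactly on cycle x sex x age group and pooled across cycles into one fit
    per sex. ``weight_by_n`` switches to WLS with the reported cell counts.
    """
    merged = reported.merge(measured, on=_CELL_KEYS, suffixes=("_rep", "_meas"))
    coefs, prov = {}, {}
    for sex in SEXES:
        sub = merged[merged["sex"] == sex]
        x = sub["mean_bmi_rep"].to_numpy(dtype=float)
        y = sub["mean_bmi_meas"].to_numpy(dtype=float)
        if len(sub) < 2:
            raise DegenerateFitError(f"fewer than 2 matched calibration cells for sex {sex!r}")
        if np.ptp(x) == 0:
            raise DegenerateFitError(f"zero variance in reported cell means for sex {sex!r}")
        X = sm.add_constant(x)
        if weight_by_n:
            model = sm.WLS(y, X, weights=sub["n_rep"].to_numpy(dtype=float))
        else:
            model = sm.OLS(y, X)
        res = model.fit()
        coefs[sex] = (float(res.params[0]), float(res.params[1]))
        prov[sex] = {
            "n_cells": int(len(sub)),
            "cycles": sorted({(int(a), int(b)) for a, b in zip(sub["cycle_start"], sub["cycle_end"])}),
        }
    return CalibrationModel(coefs, prov)


def apply_calibration(model, records):
    """Corrected BMI per record: intercept + slope x reported BMI.

    Records with missing anthropometrics get NaN (flagged missing outcome,
    excluded downstream) rather than raising.
    """
    bmi = reported_bmi(records)
    out = pd.Series(np.nan, index=records.index, dtype=float)
    for sex in records["sex"].dropna().unique():
        if sex not in model.coefficients:
            raise KeyError(f"calibration model not fitted for sex {sex!r}")
        mask = (records["sex"] == sex) & bmi.notna()
        out[mask] = model.correct(sex, bmi[mask])
    return out


def classify_obese(bmi):
    """True iff BMI >= 30 kg/m^2 (inclusive); NaN stays missing.

    Scalar in, bool out; array in, float array out with NaN preserved.
    """
    arr = np.asarray(bmi, dtype=float)
    if arr.ndim == 0:
        if np.isnan(arr):
            return np.nan
        return bool(arr >= OBESITY_BMI_THRESHOLD)
    out = (arr >= OBESITY_BMI_THRESHOLD).astype(float)
    out[np.isnan(arr)] = np.nan
    return out
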