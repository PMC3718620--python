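"""Binary outcome definitions: obesity, any activity, sufficient activity.

The sufficient-activity definition is the 2011 BRFSS standard applied
uniformly to all survey years: at least 150 moderate-equivalent minutes per
week, where one vigorous minute counts as two moderate minutes. Both the
threshold and the vigorous multiplier are configuration values so that
alternate guideline definitions amount to a parameter change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration

__all__ = [
    "SUFFICIENT_PA_THRESHOLD",
    "VIGOROUS_MULTIPLIER",
    "moderate_equivalent_minutes",
    "classify_sufficient",
    "classify_any",
    "weekly_minutes",
    "derive_outcomes",
    "OUTCOME_COLUMNS",
]

SUFFICIENT_PA_THRESHOLD = 150.0  # moderate-equivalent minutes per week
VIGOROUS_MULTIPLIER = 2.0        # 1 vigorous minute = 2 moderate minutes

#: outcome name -> microdata column holding the 0/1/missing outcome
OUTCOME_COLUMNS = {
    "obesity": "obese",
    "any_pa": "any_pa",
    "sufficient_pa": "sufficient_pa",
}


def moderate_equivalent_minutes(moderate, vigorous, multiplier=VIGOROUS_MULTIPLIER):
    """Weekly moderate-equivalent minutes: moderate + multiplier x vigorous."""
    m = np.asarray(moderate, dtype=float)
    v = np.asarray(vigorous, dtype=float)
    if np.any(m[~np.isnan(m)] < 0) or np.any(v[~np.isnan(v)] < 0):
        raise ValueError("activity minutes must be non-negative")
    out = m + multiplier * v
    return float(out) if out.ndim == 0 else out


def classify_sufficient(
    moderate, vigorous, threshold=SUFFICIENT_PA_THRESHOLD, multiplier=VIGOROUS_MULTIPLIER
):
    """1 if moderate-equivalent minutes >= threshold, 0 if below, NaN if either
    minutes field is missing (missing propagates; the record is excluded from
    the sufficient-activity model only)."""
    me = moderate_equivalent_minutes(moderate, vigorous, multiplier)
    arr = np.asarray(me, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = (arr >= threshold).astype(float)
    out[np.isnan(arr)] = np.nan
    return float(out[0]) if scalar else out


def classify_any(any_pa):
    """Pass-through of the any-activity response as 0/1/NaN.

    Accepts 'yes'/'no'/missing strings or 0/1/NaN numerics.
    """
    s = pd.Series(any_pa) if not isinstance(any_pa, pd.Series) else any_pa
    mapped = s.map({"yes": 1.0, "no": 0.0, 1: 1.0, 0: 0.0, 1.0: 1.0, 0.0: 0.0})
    bad = s.notna() & mapped.isna()
    if bad.any():
        raise ValueError(f"unrecognised any_pa value(s): {sorted(s[bad].unique())}")
    return mapped.astype(float)


def weekly_minutes(days_per_week, minutes_per_day):
    """Convert the survey's frequency x duration form to weekly minutes."""
    d = np.asarray(days_per_week, dtype=float)
    m = np.asarray(minutes_per_day, dtype=float)
    if np.any(d[~np.isnan(d)] < 0) or np.any(m[~np.isnan(m)] < 0):
        raise ValueError("frequency and duration must be non-negative")
    out = d * m
    return float(out) if out.ndim == 0 else out


def derive_outcomes(
    records,
    calibration_model=None,
    threshold=SUFFICIENT_PA_THRESHOLD,
    multiplier=VIGOROUS_MULTIPLIER,
):
    """Append the three per-record outcome columns to a microdata frame.

    ``obese`` is classified from corrected BMI when a calibration model is
    given, otherwise from raw reported BMI; ``any_pa`` is normalised to
    0/1/NaN in place; ``sufficient_pa`` applies the minutes rule. Returns a
    new frame; the input is not modified.
    """
    out = records.copy()
    if calibration_model is not None:
        bmi = calibration.apply_calibration(calibration_model, out)
    else:
        bmi = calibration.reported_bmi(out)
    out["corrected_bmi"] = bmi
    out["obese"] = calibration.classify_obese(bmi.to_numpy())
    out["any_pa"] = classify_any(out["any_pa"])
    out["sufficient_pa"] = classify_sufficient(
        out["moderate_min_week"].to_numpy(dtype=float),
        out["vigorous_min_week"].to_numpy(dtype=float),
        threshold,
        multiplier,
    )
    return out


def outcome_vector(records, outcome):
    """The 0/1/NaN outcome column for a named outcome."""
    try:
        col = OUTCOME_COLUMNS[outcome]
    except KeyError:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of {sorted(OUTCOME_COLUMNS)}")
    if col not in records:
        raise KeyError(f"records lack outcome column {col!r}; run derive_outcomes first")
    vals = records[col]
    if vals.dtype == object:
        vals = classify_any(vals)
    return pd.to_numeric(vals, errors="coerce")
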