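"""CSV/JSON interfaces between pipeline stages, with strict schema checks.

Missing values are encoded as empty CSV fields; sentinel numerics are not
recognised and fail validation. Schema violations raise
:class:`~countyprev.errors.SchemaError` carrying file, row and column so the
offending value can be located. Every writer has a reader and the round trip
is lossless for all documented fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .errors import SchemaError
from .synthetic import AGE_GROUPS, COUNTY_COVARIATES, CountyTable, RACES, SEXES

__all__ = [
    "MICRODATA_COLUMNS",
    "read_microdata",
    "write_microdata",
    "read_county_table",
    "write_county_table",
    "read_examination_cells",
    "write_examination_cells",
    "read_estimates",
    "write_estimates",
    "read_calibration",
    "write_calibration",
    "write_manifest",
    "file_digest",
]

MICRODATA_COLUMNS = [
    "year",
    "county_id",
    "sex",
    "age_group",
    "race",
    "reported_weight",
    "reported_height",
    "any_pa",
    "moderate_min_week",
    "vigorous_min_week",
]
_OPTIONAL_COLUMNS = [
    "corrected_bmi",
    "obese",
    "sufficient_pa",
    "true_bmi",
    "true_obese",
    "true_any_pa",
    "true_sufficient_pa",
]


def _check_levels(df, column, levels, path):
    vals = df[column].dropna()
    bad = ~vals.isin(levels)
    if bad.any():
        row = int(vals[bad].index[0])
        raise SchemaError(
            f"unknown level {vals[bad].iloc[0]!r} (allowed: {sorted(map(str, levels))})",
            file=path,
            row=row,
            column=column,
        )


def _check_numeric(df, column, path, minimum=None, strict=False):
    raw = df[column]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & vals.isna()
    if bad.any():
        row = int(raw[bad].index[0])
        raise SchemaError(f"non-numeric value {raw[bad].iloc[0]!r}", file=path, row=row, column=column)
    if minimum is not None:
        present = vals.dropna()
        viol = present <= minimum if strict else present < minimum
        if viol.any():
            row = int(present[viol].index[0])
            raise SchemaError(
                f"value {present[viol].iloc[0]} violates bound "
                f"({'>' if strict else '>='} {minimum})",
                file=path,
                row=row,
                column=column,
            )
    return vals


def read_microdata(path):
    """Read and validate a survey microdata CSV."""
    path = str(path)
    df = pd.read_csv(path)
    missing = [c for c in MICRODATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing}", file=path)
    if df.empty:
        return df
    _check_numeric(df, "year", path)
    _check_levels(df, "sex", SEXES, path)
    _check_levels(df, "age_group", AGE_GROUPS, path)
    _check_levels(df, "race", RACES, path)
    anypa = df["any_pa"].dropna().astype(str)
    _check_levels(df.assign(any_pa=df["any_pa"].where(df["any_pa"].isna(), anypa)),
                  "any_pa", ["yes", "no", "0", "1", "0.0", "1.0"], path)
    df["reported_weight"] = _check_numeric(df, "reported_weight", path, minimum=0, strict=True)
    df["reported_height"] = _check_numeric(df, "reported_height", path, minimum=0, strict=True)
    df["moderate_min_week"] = _check_numeric(df, "moderate_min_week", path, minimum=0)
    df["vigorous_min_week"] = _check_numeric(df, "vigorous_min_week", path, minimum=0)
    df["year"] = df["year"].astype(int)
    return df


def write_microdata(df, path):
    """Write microdata (and any derived/truth columns) to CSV."""
    cols = [c for c in MICRODATA_COLUMNS + _OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# County structure
# ---------------------------------------------------------------------------


def write_county_table(counties, outdir):
    """Write the three county files: covariate long CSV, adjacency edge list,
    race populations."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov = counties.covariates.reset_index().melt(
        id_vars=["county_id", "year"], var_name="covariate", value_name="value"
    )
    cov.to_csv(outdir / "county_covariates.csv", index=False)

    edges = sorted(
        (a, b) for a, nbrs in counties.neighbors.items() for b in nbrs if a < b
    )
    pd.DataFrame(edges, columns=["county_a", "county_b"]).to_csv(
        outdir / "adjacency.csv", index=False
    )

    counties.race_populations.reset_index().melt(
        id_vars=["county_id"], var_name="race", value_name="population"
    ).to_csv(outdir / "race_populations.csv", index=False)
    return outdir


def read_county_table(outdir):
    """Read the county files written by :func:`write_county_table`."""
    outdir = Path(outdir)
    cov_path = outdir / "county_covariates.csv"
    cov = pd.read_csv(cov_path)
    for col in ("county_id", "year", "covariate", "value"):
        if col not in cov.columns:
            raise SchemaError(f"missing column {col!r}", file=str(cov_path))
    _check_levels(cov, "covariate", COUNTY_COVARIATES, str(cov_path))
    covariates = (
        cov.pivot_table(index=["county_id", "year"], columns="covariate", values="value")
        .reindex(columns=list(COUNTY_COVARIATES))
    )
    covariates.columns.name = None

    race_path = outdir / "race_populations.csv"
    rp = pd.read_csv(race_path)
    _check_levels(rp, "race", RACES, str(race_path))
    _check_numeric(rp, "population", str(race_path), minimum=0)
    race_populations = rp.pivot_table(
        index="county_id", columns="race", values="population"
    ).reindex(columns=list(RACES))
    race_populations.columns.name = None

    adj_path = outdir / "adjacency.csv"
    edges = pd.read_csv(adj_path)
    county_ids = sorted(race_populations.index)
    neighbors = {c: set() for c in county_ids}
    for i, row in edges.iterrows():
        a, b = row["county_a"], row["county_b"]
        if a not in neighbors or b not in neighbors:
            raise SchemaError("edge references unknown county", file=str(adj_path), row=int(i))
        neighbors[a].add(b)
        neighbors[b].add(a)
    neighbors = {c: frozenset(v) for c, v in neighbors.items()}
    return CountyTable(county_ids, neighbors, covariates, race_populations)


# ---------------------------------------------------------------------------
# Examination cells, estimates, calibration
# ---------------------------------------------------------------------------

_EXAM_COLUMNS = ["cycle_start", "cycle_end", "sex", "age_group", "mean_bmi", "n"]


def write_examination_cells(cells, path):
    cells[[c for c in _EXAM_COLUMNS if c in cells.columns]].to_csv(path, index=False)
    return Path(path)


def read_examination_cells(path):
    path = str(path)
    df = pd.read_csv(path)
    missing = [c for c in _EXAM_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing}", file=path)
    _check_levels(df, "sex", SEXES, path)
    _check_levels(df, "age_group", AGE_GROUPS, path)
    _check_numeric(df, "mean_bmi", path, minimum=0, strict=True)
    return df


_ESTIMATE_COLUMNS = ["county_id", "year", "sex", "outcome", "mean", "lower", "upper"]


def write_estimates(estimates, path):
    cols = [c for c in _ESTIMATE_COLUMNS + ["n_draws"] if c in estimates.columns]
    estimates[cols].to_csv(path, index=False)
    return Path(path)


def read_estimates(path):
    path = str(path)
    df = pd.read_csv(path)
    missing = [c for c in _ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing}", file=path)
    _check_levels(df, "sex", SEXES, path)
    for col in ("mean", "lower", "upper"):
        vals = _check_numeric(df, col, path, minimum=0)
        if (vals.dropna() > 1).any():
            row = int(vals[vals > 1].index[0])
            raise SchemaError("prevalence outside [0, 1]", file=path, row=row, column=col)
    return df


def write_calibration(model, path):
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))
    return Path(path)


def read_calibration(path):
    return CalibrationModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def file_digest(path):
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, command, config, inputs=(), outputs=()):
    """Record what produced a set of outputs: config hash, seed, digests."""
    from . import __version__

    config = {k: v for k, v in sorted(config.items())}
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config": config,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "package_version": __version__,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    path = Path(outdir) / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
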