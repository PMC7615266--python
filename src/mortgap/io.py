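"""Delimited-text readers and writers for cohort tables, life tables and results.

The cohort schema is one comma-separated row per participant, header row,
ISO-8601 dates, empty field = missing. Unknown columns are preserved on a
round trip. No binary formats are used anywhere in the pipeline.
"""

from __future__ import annotations

import json
import os
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from ._vocab import EDUCATION_LEVELS, SEXES
from .projection import LifeTable

__all__ = ["SchemaError", "read_cohort", "write_cohort", "read_life_table",
           "write_life_table", "write_results"]


class SchemaError(ValueError):
    """A file does not conform to the documented cohort or life-table schema."""


MANDATORY_COLUMNS = ("id", "sex", "entry_age", "entry_date", "education")
DATE_COLUMNS = ("entry_date", "death_date")
BOOL_COLUMNS = ("diabetes_diagnosed", "cause_uncertain")
NUMERIC_COLUMNS = ("entry_age", "income_monthly", "sdi", "height", "weight",
                   "waist", "hip", "sbp", "dbp", "hba1c")


def _parse_dates(df: pd.DataFrame, col: str, path) -> None:
    if col not in df.columns:
        return
    try:
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = df[col][pd.to_datetime(df[col], format="ISO8601", errors="coerce").isna()
                      & df[col].notna()]
        row = bad.index[0] if len(bad) else "?"
        raise SchemaError(f"{path}: column {col!r}, row {row}: not an ISO date") from exc


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table; missing fields are empty strings."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=True, na_values=[""])
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: mandatory column {col!r} is missing")
    for col in DATE_COLUMNS:
        _parse_dates(df, col, path)
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: column {col!r} is not numeric") from exc
    for col in BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False,
                 "true": True, "false": False, 1: True, 0: False, 1.0: True, 0.0: False})
            df[col] = df[col].fillna(False).astype(bool)
    bad_sex = df["sex"].dropna()[~df["sex"].dropna().isin(SEXES)]
    if len(bad_sex):
        raise SchemaError(f"{path}: column 'sex', row {bad_sex.index[0]}: "
                          f"unknown value {bad_sex.iloc[0]!r}")
    bad_edu = df["education"].dropna()[~df["education"].dropna().isin(EDUCATION_LEVELS)]
    if len(bad_edu):
        raise SchemaError(f"{path}: column 'education', row {bad_edu.index[0]}: "
                          f"unknown value {bad_edu.iloc[0]!r}")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    """Write a cohort table: ISO dates, empty field for missing values."""
    path = Path(path)
    out = cohort.copy()
    for col in DATE_COLUMNS:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")
    return path


def read_life_table(path) -> LifeTable:
    """Read a life table (sex, age_lo, age_hi, rate) from delimited text."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"sex", "age_lo", "age_hi", "rate"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: life table missing columns {sorted(missing)}")
    for col in ("age_lo", "age_hi", "rate"):
        df[col] = pd.to_numeric(df[col])
    return LifeTable(df)


def write_life_table(lt: LifeTable, path) -> Path:
    lt.table.to_csv(Path(path), index=False)
    return Path(path)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, (pd.Timestamp,)):
            return o.isoformat()
        return super().default(o)


def write_results(outdir, artifacts: Mapping[str, object],
                  manifest: Mapping[str, object] | None = None) -> dict[str, Path]:
    """Serialise a bundle of result artifacts under ``outdir``.

    DataFrames become CSV files, everything else JSON; a ``manifest.json``
    (run configuration hash, seed, artifact list) indexes the bundle.
    """
    outdir = Path(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, obj in artifacts.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, index=False)
        else:
            p = outdir / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, cls=_JSONEncoder)
        paths[name] = p
    manifest = dict(manifest or {})
    manifest["artifacts"] = sorted(str(p.name) for p in paths.values())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, cls=_JSONEncoder)
    paths["manifest"] = outdir / "manifest.json"
    return paths
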