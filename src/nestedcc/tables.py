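"""Schemas and delimited-text I/O for the four longitudinal EHR tables.

Tables live on disk as comma-separated text with a header row; dates are
ISO-8601 strings.  Inside the package dates are held as numpy
``datetime64[D]`` and all arithmetic is in integer days.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PATIENT_COLUMNS = [
    "patient_id",
    "gender",
    "year_of_birth",
    "practice_id",
    "registration_start",
    "registration_end",
    "ethnicity",
    "latent_severity",
]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "drug_class", "agent", "duration_days"]
EVENT_COLUMNS = ["patient_id", "date", "code_category", "value"]
DEATH_COLUMNS = ["patient_id", "death_date", "cause_category"]

TABLE_SCHEMAS = {
    "patients": PATIENT_COLUMNS,
    "prescriptions": PRESCRIPTION_COLUMNS,
    "clinical_events": EVENT_COLUMNS,
    "deaths": DEATH_COLUMNS,
}

_DATE_COLUMNS = {
    "patients": ["registration_start", "registration_end"],
    "prescriptions": ["date"],
    "clinical_events": ["date"],
    "deaths": ["death_date"],
}


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def as_days(series_or_array) -> np.ndarray:
    """Return a ``datetime64[D]`` numpy view of a date column."""
    if isinstance(series_or_array, pd.Series):
        series_or_array = series_or_array.to_numpy()
    return np.asarray(series_or_array, dtype="datetime64[D]")


def reindex_dates(series: pd.Series, ids) -> np.ndarray:
    """Align a per-patient date Series to ``ids`` as datetime64[D] with NaT."""
    aligned = series.reindex(ids)
    return pd.to_datetime(aligned).to_numpy(dtype="datetime64[D]")


def days_between(later, earlier) -> np.ndarray:
    """Integer day counts ``later - earlier``."""
    return (as_days(later) - as_days(earlier)).astype(np.int64)


def _parse_dates_strict(df: pd.DataFrame, name: str, path=None) -> pd.DataFrame:
    for col in _DATE_COLUMNS[name]:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            lineno = int(bad.idxmax()) + 2  # header occupies line 1
            where = f"{path}:" if path is not None else ""
            raise SchemaError(
                f"{where}{lineno}: malformed ISO-8601 date {raw[bad.idxmax()]!r} "
                f"in column {col!r} of table {name!r}"
            )
        df[col] = parsed.to_numpy(dtype="datetime64[D]")
    return df


def validate_schema(df: pd.DataFrame, name: str) -> None:
    expected = TABLE_SCHEMAS[name]
    if list(df.columns) != expected:
        # latent_severity may legitimately be absent downstream: analysis
        # modules never read it.
        if name == "patients" and list(df.columns) == expected[:-1]:
            return
        raise SchemaError(
            f"table {name!r} columns {list(df.columns)} != expected {expected}"
        )


def write_table(df: pd.DataFrame, name: str, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.csv"
    out = df.copy()
    for col in _DATE_COLUMNS[name]:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def read_table(path, name: str) -> pd.DataFrame:
    path = Path(path)
    # keep_default_na=False: empty strings encode missing categorical values
    # and must survive a round trip unchanged
    df = pd.read_csv(
        path, dtype={"patient_id": str, "practice_id": str}, keep_default_na=False
    )
    for col in df.columns:
        if col in ("year_of_birth", "duration_days"):
            df[col] = pd.to_numeric(df[col]).astype(np.int64)
        elif col == "latent_severity":
            df[col] = pd.to_numeric(df[col])
    validate_schema(df, name)
    return _parse_dates_strict(df, name, path=path)


def read_tables(in_dir) -> dict[str, pd.DataFrame]:
    in_dir = Path(in_dir)
    return {name: read_table(in_dir / f"{name}.csv", name) for name in TABLE_SCHEMAS}


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> None:
    for name, df in tables.items():
        write_table(df, name, out_dir)
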