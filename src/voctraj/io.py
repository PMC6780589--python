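"""CSV schemas and validated readers/writers for the three input tables.

Long-format tables: one patient, one stay or one measurement per row.
Timestamps are ISO-8601; multi-valued code/drug cells are
semicolon-separated.  Malformed rows are rejected with row-numbered
messages (row numbers count the header as line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_patients",
    "read_stays",
    "read_measurements",
    "write_patients",
    "write_stays",
    "write_measurements",
]


class SchemaError(ValueError):
    pass


PATIENT_REQUIRED = ["patient_id", "sex", "genotype"]
STAY_REQUIRED = [
    "stay_id",
    "patient_id",
    "admission",
    "discharge",
    "icu_flag",
    "severity_level",
    "transfusion_flag",
    "icd_codes",
    "drugs",
]
MEASUREMENT_REQUIRED = ["stay_id", "variable", "value"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _row_numbers(index: pd.Index) -> list[int]:
    # +2: header line plus 1-based counting
    return [int(i) + 2 for i in index]


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, PATIENT_REQUIRED, path)
    bad_sex = df.index[~df["sex"].isin(["female", "male"])]
    if len(bad_sex):
        raise SchemaError(
            f"{path}: invalid sex value at row(s) {_row_numbers(bad_sex)} "
            "(expected 'female' or 'male')"
        )
    if "steady_state_hb" in df.columns:
        hb = pd.to_numeric(df["steady_state_hb"], errors="coerce")
        bad = df.index[hb.notna() & ~hb.between(3, 20, inclusive="neither")]
        if len(bad):
            raise SchemaError(
                f"{path}: steady_state_hb outside (3, 20) g/dL at row(s) "
                f"{_row_numbers(bad)}"
            )
    return df


def read_stays(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"stay_id": str, "patient_id": str, "icd_codes": str, "drugs": str}
    )
    _require_columns(df, STAY_REQUIRED, path)
    if df.empty:
        df["admission"] = pd.to_datetime(df["admission"])
        df["discharge"] = pd.to_datetime(df["discharge"])
        return df
    for col in ("admission", "discharge"):
        parsed = pd.to_datetime(df[col], errors="coerce")
        bad = df.index[parsed.isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: unparseable {col} timestamp at row(s) {_row_numbers(bad)}"
            )
        df[col] = parsed
    bad_order = df.index[df["discharge"] <= df["admission"]]
    if len(bad_order):
        raise SchemaError(
            f"{path}: discharge not after admission at row(s) "
            f"{_row_numbers(bad_order)}"
        )
    sev = pd.to_numeric(df["severity_level"], errors="coerce")
    bad_sev = df.index[~sev.isin([1, 2, 3, 4])]
    if len(bad_sev):
        raise SchemaError(
            f"{path}: severity_level not in 1..4 at row(s) {_row_numbers(bad_sev)}"
        )
    df["severity_level"] = sev.astype(int)
    for col in ("icu_flag", "transfusion_flag"):
        df[col] = _parse_bool(df[col], col, path)
    df["icd_codes"] = df["icd_codes"].fillna("")
    df["drugs"] = df["drugs"].fillna("")
    return df


def _parse_bool(series: pd.Series, name: str, path) -> pd.Series:
    mapping = {
        "true": True,
        "false": False,
        "1": True,
        "0": False,
        "yes": True,
        "no": False,
    }
    text = series.astype(str).str.strip().str.lower()
    bad = series.index[~text.isin(mapping)]
    if len(bad):
        raise SchemaError(
            f"{path}: invalid boolean {name} at row(s) {_row_numbers(bad)}"
        )
    return text.map(mapping)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stay_id": str, "variable": str})
    _require_columns(df, MEASUREMENT_REQUIRED, path)
    if "time_hours" not in df.columns and "timestamp" not in df.columns:
        raise SchemaError(f"{path}: need a time_hours or timestamp column")
    if df.empty:
        return df
    val = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[val.isna() | ~np.isfinite(val)]
    if len(bad):
        raise SchemaError(
            f"{path}: non-finite value at row(s) {_row_numbers(bad)}"
        )
    df["value"] = val.astype(float)
    if "time_hours" in df.columns:
        t = pd.to_numeric(df["time_hours"], errors="coerce")
        bad_t = df.index[t.isna() | (t < 0)]
        if len(bad_t):
            raise SchemaError(
                f"{path}: invalid time_hours (missing or negative) at row(s) "
                f"{_row_numbers(bad_t)}"
            )
        df["time_hours"] = t.astype(float)
    if "unit" not in df.columns:
        df["unit"] = ""
    else:
        df["unit"] = df["unit"].fillna("")
    return df


def write_patients(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_stays(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("admission", "discharge"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
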