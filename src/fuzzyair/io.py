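"""CSV and configuration file handling shared by the CLI and library.

Daily series are comma-delimited UTF-8 with a header row and ISO-8601
dates.  Required columns: ``date, pm10, o3, so2`` plus either
``temp_apparent`` or the pair ``temp`` (ambient temperature, degC) and
``rh`` (relative humidity, %).  ``admissions`` is optional (needed only
for validation).  Missing values are empty fields; malformed cells are
reported with their file line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["read_series", "write_series", "read_predictions",
           "write_predictions"]

_EXPOSURE_COLUMNS = ("pm10", "o3", "so2")
_OPTIONAL_NUMERIC = ("temp", "rh", "temp_apparent", "admissions")


def _coerce_numeric(df: pd.DataFrame, raw: pd.DataFrame, col: str,
                    path) -> None:
    values = pd.to_numeric(raw[col], errors="coerce")
    bad = values.isna() & raw[col].notna() & (raw[col].str.strip() != "")
    if bad.any():
        # +2: header is line 1 and pandas indexes from 0.
        lines = [str(i + 2) for i in bad[bad].index[:10]]
        raise InvalidInputError(
            f"{path}: column {col!r} has non-numeric values on line(s) "
            f"{', '.join(lines)}")
    df[col] = values.astype(float)


def read_series(path) -> pd.DataFrame:
    """Read a daily exposure(/admissions) series from CSV.

    Returns a frame with a ``date`` column (datetime.date) and float columns
    for every recognized numeric field present in the file; missing cells
    become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"input file not found: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip().lower() for c in raw.columns]
    if "date" not in raw.columns:
        raise InvalidInputError(f"{path}: missing required column 'date'")
    missing = [c for c in _EXPOSURE_COLUMNS if c not in raw.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing required column(s) {', '.join(missing)}")
    has_at = "temp_apparent" in raw.columns
    has_ta_rh = "temp" in raw.columns and "rh" in raw.columns
    if not (has_at or has_ta_rh):
        raise InvalidInputError(
            f"{path}: need either a 'temp_apparent' column or both "
            "'temp' and 'rh'")
    try:
        dates = pd.to_datetime(raw["date"], format="ISO8601").dt.date
    except ValueError as exc:
        raise InvalidInputError(
            f"{path}: dates must be ISO-8601 ({exc})") from exc
    df = pd.DataFrame({"date": dates})
    for col in (*_EXPOSURE_COLUMNS, *_OPTIONAL_NUMERIC):
        if col in raw.columns:
            _coerce_numeric(df, raw, col, path)
    return df


def write_series(series: pd.DataFrame, path) -> None:
    """Write a daily series as CSV with ISO dates and empty-field missing."""
    out = series.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False, float_format="%.6g")


def write_predictions(predictions: pd.DataFrame, path) -> None:
    """Write a (date, predicted) table as CSV."""
    out = predictions[["date", "predicted"]].copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False, float_format="%.6g")


def read_predictions(path) -> pd.DataFrame:
    """Read a (date, predicted) CSV written by :func:`write_predictions`."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"predictions file not found: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip().lower() for c in raw.columns]
    for col in ("date", "predicted"):
        if col not in raw.columns:
            raise InvalidInputError(f"{path}: missing required column {col!r}")
    df = pd.DataFrame(
        {"date": pd.to_datetime(raw["date"], format="ISO8601").dt.date})
    _coerce_numeric(df, raw, "predicted", path)
    return df
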