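"""CSV interchange for participant records.

Dialect: UTF-8, comma-separated, header row, ``.`` decimal. Column order is
stable: identifiers and demographics first, then raw test scores, then the
clock subscores, then ``delayed_recall`` and (optionally) ``true_state``.
An absent ``dct_summary`` (empty cell) marks an unanalyzable clock and is
carried through as NaN, never imputed.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = ["RecordValidationError", "read_records", "write_records", "validate_records"]

#: Required columns, in canonical order (subscores slot in after dct_summary).
BASE_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "education_years",
    "race",
    "ethnicity",
    "ravlt_long_delay",
    "tmtb_seconds",
    "faq",
    "mmse",
    "dct_summary",
]
TAIL_COLUMNS = ["delayed_recall"]

_SUBSCORE_RE = re.compile(r"^dct_sub_\d{2}$")

_CATEGORIES = {
    "sex": {"female", "male"},
    "race": {"White", "Non-White"},
    "ethnicity": {"Hispanic", "Non-Hispanic"},
}

# column -> (low, high); bounds inclusive unless noted
_RANGES = {
    "ravlt_long_delay": (0.0, 15.0),
    "faq": (0.0, 30.0),
    "mmse": (0.0, 30.0),
    "dct_summary": (0.0, 100.0),
    "delayed_recall": (0.0, 3.0),
}


class RecordValidationError(ValueError):
    """A record file violated the schema; the message names row/column."""


def _fail(column: str, rows=None, reason: str = "") -> None:
    loc = f" (rows {list(rows)[:5]})" if rows is not None and len(rows) else ""
    raise RecordValidationError(f"column '{column}': {reason}{loc}")


def validate_records(df: pd.DataFrame) -> None:
    """Validate schema, ranges and uniqueness; raise on the first violation."""
    for col in BASE_COLUMNS + TAIL_COLUMNS:
        if col not in df.columns:
            raise RecordValidationError(f"missing required column '{col}'")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        _fail("participant_id", reason=f"duplicate id {dup!r}")
    for col, allowed in _CATEGORIES.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            _fail(col, df.index[bad], f"values outside {sorted(allowed)}")
    numeric = ["age", "education_years", "ravlt_long_delay", "tmtb_seconds",
               "faq", "mmse", "dct_summary", "delayed_recall"]
    numeric += [c for c in df.columns if _SUBSCORE_RE.match(c)]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        unparseable = vals.isna() & df[col].notna()
        if unparseable.any():
            _fail(col, df.index[unparseable], "unparseable value")
        if col != "dct_summary":  # absent dct_summary marks an unanalyzable clock
            missing = df[col].isna()
            if missing.any():
                _fail(col, df.index[missing], "missing value")
    for col, (low, high) in _RANGES.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = (vals < low) | (vals > high)
        if bad.any():
            _fail(col, df.index[bad], f"value outside [{low}, {high}]")
    bad = pd.to_numeric(df["tmtb_seconds"]) <= 0
    if bad.any():
        _fail("tmtb_seconds", df.index[bad], "must be > 0")
    for col in [c for c in df.columns if _SUBSCORE_RE.match(c)]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = (vals < 0) | (vals > 100)
        if bad.any():
            _fail(col, df.index[bad], "value outside [0, 100]")


def write_records(records: pd.DataFrame, destination) -> None:
    """Write a population to CSV in the documented dialect and column order."""
    sub_cols = sorted(c for c in records.columns if _SUBSCORE_RE.match(c))
    cols = BASE_COLUMNS + sub_cols + TAIL_COLUMNS
    if "true_state" in records.columns:
        cols = cols + ["true_state"]
    records[cols].to_csv(destination, index=False)


def read_records(source) -> pd.DataFrame:
    """Read and validate a population CSV; returns typed columns.

    Raises :class:`RecordValidationError` for missing columns, unparseable
    values or out-of-range scores, identifying the offending column and rows.
    """
    df = pd.read_csv(source, dtype={"participant_id": str})
    validate_records(df)
    for col in ("faq", "mmse", "delayed_recall"):
        df[col] = df[col].astype(np.int64)
    for col in ("age", "education_years", "ravlt_long_delay", "tmtb_seconds",
                "dct_summary"):
        df[col] = df[col].astype(float)
    for col in df.columns:
        if _SUBSCORE_RE.match(col):
            df[col] = df[col].astype(float)
    return df
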