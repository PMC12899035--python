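"""Raw intake-export cleaning.

Turns a messy raw table (nulls, text labels, non-numeric junk) into a
standardized fully numeric table with the ethanol-stability label as the
leading column and the indicators in their original order. Rows are the
unit of integrity: any row with a null or an unparseable cell is dropped
whole, so every retained record is internally consistent. "positive" /
"negative" tokens (case-insensitive) are encoded as 1/0 in the label and
AD columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import INDICATOR_COLUMNS, LABEL_COLUMN
from .errors import SchemaError

__all__ = ["CleanTable", "clean_table", "write_clean_csv", "load_clean_csv"]

REQUIRED_COLUMNS = [LABEL_COLUMN] + INDICATOR_COLUMNS
_CATEGORICAL_COLUMNS = [LABEL_COLUMN, "AD1", "AD2"]

# leading numeric value with an optional trailing unit suffix (g, °T, %, ...)
_NUMERIC_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*[a-zA-Z°%/ ]*\s*$"
)


def _parse_cell(value) -> float:
    """Parse one cell to float; NaN when syntactically non-numeric."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    m = _NUMERIC_RE.match(str(value))
    return float(m.group(1)) if m else np.nan


def _parse_categorical(value) -> float:
    if isinstance(value, str):
        token = value.strip().lower()
        if token == "positive":
            return 1.0
        if token == "negative":
            return 0.0
    v = _parse_cell(value)
    return v if v in (0.0, 1.0) else np.nan


@dataclass
class CleanTable:
    """A fully numeric table, label first then the 15 indicators."""

    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        self.records = self.records[REQUIRED_COLUMNS].reset_index(drop=True)

    def __len__(self):
        return len(self.records)

    def __eq__(self, other):
        return isinstance(other, CleanTable) and self.records.equals(other.records)

    @property
    def labels(self) -> np.ndarray:
        return self.records[LABEL_COLUMN].to_numpy(dtype=np.int64)

    @property
    def features(self) -> pd.DataFrame:
        return self.records[INDICATOR_COLUMNS]

    def n_positive(self) -> int:
        return int(self.labels.sum())


def clean_table(raw: pd.DataFrame) -> CleanTable:
    """Standardize a raw export.

    Steps: verify the 16-column schema; parse every cell (stripping
    whitespace and unit suffixes, mapping positive/negative to 1/0 in the
    label and AD columns); drop every row containing a null or a cell that
    remains non-numeric; reorder columns with the label first.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    parsed = {}
    for col in REQUIRED_COLUMNS:
        fn = _parse_categorical if col in _CATEGORICAL_COLUMNS else _parse_cell
        parsed[col] = raw[col].map(fn).astype(np.float64)
    frame = pd.DataFrame(parsed)
    frame = frame.dropna(axis=0, how="any").reset_index(drop=True)
    for col in _CATEGORICAL_COLUMNS:
        frame[col] = frame[col].astype(np.int64)
    return CleanTable(frame)


def write_clean_csv(clean: CleanTable, path) -> None:
    """Write as UTF-8 comma-separated CSV with a header row."""
    clean.records.to_csv(path, index=False, encoding="utf-8")


def load_clean_csv(path) -> CleanTable:
    """Load a previously written clean CSV; validates schema and numerics."""
    try:
        frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except Exception as exc:  # malformed file
        raise SchemaError(f"could not parse '{path}': {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"'{path}': missing required column(s): {', '.join(missing)}")
    for col in REQUIRED_COLUMNS:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            row = int(np.flatnonzero(bad.to_numpy() | frame[col].isna().to_numpy())[0])
            raise SchemaError(
                f"'{path}': non-numeric or missing value in column '{col}' at data row {row}"
            )
        frame[col] = numeric
    for col in _CATEGORICAL_COLUMNS:
        frame[col] = frame[col].astype(np.int64)
    return CleanTable(frame)
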