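"""Feature-table CSV interchange.

The feature CSV is the interface between the two pipeline halves
(simulation/extraction and classification/similarity): columns
``fly_id, genotype, sf0.014_tf1, ..., sf1.76_tf36`` in the fixed canonical
order. The same format accepts externally produced tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import canonical_columns
from .exceptions import SchemaError, ValidationError

_META_COLS = ["fly_id", "genotype"]


def expected_columns() -> list:
    return _META_COLS + canonical_columns()


def validate_features(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema (exact canonical columns) and values (finite, >= 0)."""
    expected = expected_columns()
    got = list(table.columns)
    missing = [c for c in expected if c not in got]
    extra = [c for c in got if c not in expected]
    if extra:
        raise SchemaError(f"unexpected column(s): {extra}")
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    if got != expected:
        raise SchemaError("columns are not in canonical order")
    amps = table[canonical_columns()]
    if amps.isna().any().any():
        bad = amps.isna().any(axis=1)
        rows = list(table.index[bad][:5])
        raise ValidationError(f"NaN amplitude(s) in row(s) {rows}")
    values = amps.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite amplitude(s) in feature table")
    return table


def write_features_csv(table: pd.DataFrame, path) -> Path:
    """Write a validated feature table with full float precision
    (17 significant digits, lossless round-trip)."""
    validate_features(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_features_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype={"fly_id": str, "genotype": str})
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed CSV {path}: {exc}") from exc
    # re-parse amplitudes strictly so a malformed row is named
    for col in table.columns:
        if col in _META_COLS:
            continue
        try:
            table[col] = pd.to_numeric(table[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(table[col], errors="coerce")
            rows = list(table.index[bad.isna() & table[col].notna()][:5])
            raise SchemaError(
                f"column {col!r}: non-numeric value(s) in row(s) {rows}"
            ) from exc
    return validate_features(table)
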