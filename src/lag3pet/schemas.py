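"""Content validation for the CSV interchange files.

``validate_schema`` checks column names, types, value constraints and
per-region time monotonicity, returning a list of human-readable errors
(file, row, column) rather than raising on content problems.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "validate_schema", "SCHEMAS"]


@dataclass(frozen=True)
class SchemaError:
    file: str
    row: int | None      # 1-based data row, None for file-level problems
    column: str | None
    message: str

    def __str__(self) -> str:
        loc = self.file
        if self.row is not None:
            loc += f", row {self.row}"
        if self.column:
            loc += f", column {self.column!r}"
        return f"{loc}: {self.message}"


SCHEMAS: dict[str, dict] = {
    "plasma": {
        "columns": ["patient_id", "cycle", "time_h", "conc_pct_ia_per_l"],
        "positive": ["time_h"],
        "nonneg": ["conc_pct_ia_per_l"],
        "group_time": (["patient_id", "cycle"], "time_h"),
    },
    "tac": {
        "columns": ["patient_id", "region_id", "region_type", "cycle",
                    "time_h", "conc_bq_per_ml"],
        "positive": ["time_h"],
        "nonneg": ["conc_bq_per_ml"],
        "enum": {"region_type": {"organ", "tumor", "plasma", "blood"}},
        "group_time": (["patient_id", "region_id", "cycle"], "time_h"),
    },
    "injections": {
        "columns": ["patient_id", "cycle", "activity_mbq", "mass_mg",
                    "weight_kg", "t0_iso8601"],
        "positive": ["activity_mbq", "mass_mg", "weight_kg"],
    },
    "lesions": {
        "columns": ["patient_id", "lesion_id", "volume_ml", "infiltration",
                    "ki_spec_ul_g_h", "ihc_lag3_pct", "site_class"],
        "positive": ["volume_ml"],
        "nonneg": ["ki_spec_ul_g_h"],
        "range": {"infiltration": (0.0, 1.0), "ihc_lag3_pct": (0.0, 100.0)},
        "enum": {"site_class": {"lymph-node", "other"}},
    },
    "uptake": {
        "columns": ["patient_id", "region_id", "region_type", "cycle",
                    "mass_dose_mg", "time_h", "measure_kind", "value"],
        "positive": ["time_h", "mass_dose_mg"],
        "nonneg": ["value"],
        "enum": {"measure_kind": {"tissue_to_plasma", "suv_peak",
                                  "pct_ia_per_l"}},
    },
}


def validate_schema(path, schema_id: str) -> list[SchemaError]:
    """Validate a CSV file against one of the interchange schemas.

    Returns an empty list on success; content problems are reported, not
    raised. An unreadable file or unknown schema raises.
    """
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}")
    schema = SCHEMAS[schema_id]
    path = Path(path)
    name = path.name
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # unreadable content is a file-level error
        return [SchemaError(name, None, None, f"cannot parse CSV: {exc}")]

    errors: list[SchemaError] = []
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        errors.append(SchemaError(name, None, None,
                                  f"missing columns {missing}"))
        return errors
    extra = [c for c in df.columns if c not in schema["columns"]]
    if extra:
        errors.append(SchemaError(name, None, None,
                                  f"unexpected columns {extra}"))

    def numeric(col):
        return pd.to_numeric(df[col], errors="coerce")

    for col in schema.get("positive", []):
        vals = numeric(col)
        for idx in df.index[vals.isna() | (vals <= 0)]:
            errors.append(SchemaError(name, int(idx) + 1, col,
                                      "must be a number > 0"))
    for col in schema.get("nonneg", []):
        vals = numeric(col)
        for idx in df.index[vals.isna() | (vals < 0)]:
            errors.append(SchemaError(name, int(idx) + 1, col,
                                      "must be a number >= 0"))
    for col, (lo, hi) in schema.get("range", {}).items():
        vals = numeric(col)
        for idx in df.index[vals.isna() | (vals < lo) | (vals > hi)]:
            errors.append(SchemaError(name, int(idx) + 1, col,
                                      f"must be in [{lo}, {hi}]"))
    for col, allowed in schema.get("enum", {}).items():
        bad = ~df[col].astype(str).isin(allowed)
        for idx in df.index[bad]:
            errors.append(SchemaError(name, int(idx) + 1, col,
                                      f"must be one of {sorted(allowed)}"))

    if "group_time" in schema and not errors:
        keys, tcol = schema["group_time"]
        for group, sub in df.groupby(keys, sort=False):
            t = sub[tcol].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                errors.append(SchemaError(
                    name, int(sub.index[0]) + 1, tcol,
                    f"times not strictly increasing for {keys}={group}"))
    return errors
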