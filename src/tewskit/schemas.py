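"""Input-table schema validation and CSV round-tripping."""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError

SCHEMAS = {
    "observations": {
        "columns": ["stay_id", "variable", "minutes", "value", "unit"],
        "numeric": ["minutes", "value"],
    },
    "interventions": {
        "columns": ["stay_id", "kind", "agent", "start_min", "end_min",
                    "rate", "rate_unit"],
        "numeric": ["start_min", "end_min"],
    },
    "stays": {
        "columns": ["stay_id", "admit_iso", "discharge_iso", "age", "gender",
                    "icd_codes", "culture_minutes"],
        "numeric": ["age"],
    },
}


def validate_schema(table, schema_name: str) -> pd.DataFrame:
    """Check a table (path or DataFrame) against a named schema.

    Missing columns are a hard failure; non-numeric entries in numeric columns
    are reported with their row numbers.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, dtype={"stay_id": str})
    spec = SCHEMAS[schema_name]
    missing = [c for c in spec["columns"] if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{schema_name}: missing column(s) {missing}")
    for col in spec["numeric"]:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table[col].notna() & coerced.isna()
        if bad.any():
            rows = (table.index[bad] + 2).tolist()[:5]  # 1-based + header
            raise SchemaError(
                f"{schema_name}: non-numeric {col!r} at file row(s) {rows}")
        table[col] = coerced
    return table


def read_inputs(obs_path, interv_path, stays_path):
    obs = validate_schema(obs_path, "observations")
    interv = validate_schema(interv_path, "interventions")
    stays = validate_schema(stays_path, "stays")
    unknown = set(obs["stay_id"]) - set(stays["stay_id"])
    if unknown:
        raise SchemaError(
            f"observations reference unknown stay(s): {sorted(unknown)[:5]}")
    return obs, interv, stays
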