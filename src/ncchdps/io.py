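"""CSV persistence for the raw claims-style tables.

Round-trip contract: ``read_tables(write_tables(t, d)) == t`` for
schema-conformant tables, including empty ones.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import (
    CODE_EVENT_COLUMNS,
    DISPENSATION_COLUMNS,
    GROUND_TRUTH_COLUMNS,
    PERSON_COLUMNS,
    RawTables,
)

_SCHEMAS = {
    "persons": PERSON_COLUMNS,
    "dispensations": DISPENSATION_COLUMNS,
    "code_events": CODE_EVENT_COLUMNS,
}

_DTYPES = {
    "person_id": str,
    "birth_date": str,
    "sex": str,
    "cohort_entry_date": str,
    "end_date": str,
    "drug_class": str,
    "dispense_date": str,
    "din_code": str,
    "dimension": str,
    "code": str,
    "event_date": str,
    "income_quintile": "int64",
    "days_supplied": "int64",
    "died": "bool",
}


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong shape."""


def validate_tables(tables: RawTables) -> None:
    """Check column schemas and referential integrity; raise SchemaError."""
    for name, columns in _SCHEMAS.items():
        df = getattr(tables, name)
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(f"table {name!r} is missing column(s) {missing}")
    known = set(tables.persons["person_id"])
    for name in ("dispensations", "code_events"):
        df = getattr(tables, name)
        if len(df) and not set(df["person_id"]).issubset(known):
            stray = sorted(set(df["person_id"]) - known)[:5]
            raise SchemaError(f"table {name!r} has unknown person_id(s) {stray}")
    if len(tables.dispensations) and (tables.dispensations["days_supplied"] <= 0).any():
        raise SchemaError("dispensations.days_supplied must be > 0")


def write_tables(
    tables: RawTables,
    directory: str | Path,
    ground_truth: pd.DataFrame | None = None,
) -> None:
    """Write persons.csv, dispensations.csv, code_events.csv (and, when
    given, ground_truth.csv) into ``directory``."""
    validate_tables(tables)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, columns in _SCHEMAS.items():
        getattr(tables, name)[columns].to_csv(directory / f"{name}.csv", index=False)
    if ground_truth is not None:
        ground_truth[GROUND_TRUTH_COLUMNS].to_csv(
            directory / "ground_truth.csv", index=False
        )


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: _DTYPES[c] for c in columns if c in _DTYPES})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"file {path.name!r} is missing column(s) {missing}")
    if df.empty:
        # Pin empty-table dtypes so the round trip is exact.
        df = df.astype({c: _DTYPES[c] for c in columns if c in _DTYPES})
    return df[columns]


def read_tables(directory: str | Path) -> RawTables:
    """Read the three raw tables back from ``directory``."""
    directory = Path(directory)
    tables = RawTables(
        persons=_read_csv(directory / "persons.csv", PERSON_COLUMNS),
        dispensations=_read_csv(directory / "dispensations.csv", DISPENSATION_COLUMNS),
        code_events=_read_csv(directory / "code_events.csv", CODE_EVENT_COLUMNS),
    )
    validate_tables(tables)
    return tables


def read_ground_truth(directory: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        Path(directory) / "ground_truth.csv", dtype={"person_id": str}
    )[GROUND_TRUTH_COLUMNS]
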