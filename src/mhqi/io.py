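"""Reading and writing regional bundles of delimited event tables.

A bundle is one directory per region holding ``patients.csv``,
``contacts.csv``, ``admissions.csv``, ``dispensations.csv``,
``residential.csv``, ``lab_services.csv`` and ``diagnoses.csv``
(comma-separated, header row, ISO-8601 dates, UTF-8), plus a small
``meta.json`` sidecar with the region label, ICD dialect and data horizon.
Loading enforces the schemas, parses dates with row-level error reporting,
drops events that reference unknown patients (real-world linkage loss) and
returns an audit :class:`LoadReport` alongside the linked store.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from .model import (
    DATE_COLUMNS,
    OPTIONAL_DATE_COLUMNS,
    SCHEMAS,
    EventStore,
)


class SchemaError(ValueError):
    """A bundle file is missing or malformed at the schema level."""


class RowError(ValueError):
    """A specific row of a bundle file cannot be parsed."""


@dataclass
class LoadReport:
    """Per-file audit of a bundle load: rows read and rows dropped because
    they referenced a patient absent from the registry."""

    region: str
    rows: dict[str, int] = field(default_factory=dict)
    dropped_unknown_patient: dict[str, int] = field(default_factory=dict)

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped_unknown_patient.values())

    def to_json(self, path) -> None:
        payload = {
            "region": self.region,
            "rows": self.rows,
            "dropped_unknown_patient": self.dropped_unknown_patient,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _parse_dates(df: pd.DataFrame, table: str, path: Path) -> pd.DataFrame:
    for col in DATE_COLUMNS[table]:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad = parsed.isna() & ~blank
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based
            raise RowError(
                f"{path.name}, line {line}: unparseable date {raw[bad.idxmax()]!r} in column {col!r}"
            )
        if not (table, col) in OPTIONAL_DATE_COLUMNS and (parsed.isna() & blank).any():
            line = int((parsed.isna() & blank).idxmax()) + 2
            raise RowError(f"{path.name}, line {line}: missing date in column {col!r}")
        df[col] = parsed
    return df


def read_region(bundle_dir, maps=None) -> tuple[EventStore, LoadReport]:
    """Load one region's bundle into a linked :class:`EventStore`.

    Rows whose ``patient_id`` is absent from the registry are dropped and
    counted in the returned :class:`LoadReport`; schema violations and
    unparseable dates raise instead.  ``maps`` is accepted for interface
    symmetry (code lists are applied downstream, not at load time).
    """
    bundle = Path(bundle_dir)
    meta_path = bundle / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    tables: dict[str, pd.DataFrame] = {}
    report = LoadReport(region=meta.get("region", bundle.name))
    for name, cols in SCHEMAS.items():
        path = bundle / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing bundle file {path.name}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace({"": None})
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
        df = df[list(cols)]
        df = _parse_dates(df, name, path)
        if name == "dispensations":
            df["n_ddd"] = pd.to_numeric(df["n_ddd"], errors="raise").astype(float)
        report.rows[name] = len(df)
        tables[name] = df

    known = set(tables["patients"]["patient_id"])
    for name, df in tables.items():
        if name == "patients":
            continue
        keep = df["patient_id"].isin(known)
        report.dropped_unknown_patient[name] = int((~keep).sum())
        tables[name] = df[keep].reset_index(drop=True)

    unavailable = tuple(meta.get("unavailable_services", ()))
    if meta:
        horizon = (
            date.fromisoformat(meta["horizon"][0]),
            date.fromisoformat(meta["horizon"][1]),
        )
        dialect = meta.get("icd_dialect", "icd10")
    else:
        all_dates = pd.concat(
            [tables[t][c].dropna() for t in SCHEMAS for c in DATE_COLUMNS[t] if c != "birth_date"],
            ignore_index=True,
        )
        if len(all_dates):
            horizon = (all_dates.min().date(), all_dates.max().date())
        else:
            horizon = (date(1900, 1, 1), date(2100, 1, 1))
        dialect = "icd10"

    store = EventStore(
        region=report.region,
        horizon=horizon,
        icd_dialect=dialect,
        unavailable_services=unavailable,
    )
    for name, df in tables.items():
        setattr(store, name, df)
    store.validate()
    return store, report


def write_region(store: EventStore, bundle_dir) -> None:
    """Write a store back to a bundle directory (ISO dates, canonical row
    order, so write → read round-trips exactly)."""
    bundle = Path(bundle_dir)
    bundle.mkdir(parents=True, exist_ok=True)
    canon = store.canonical()
    for name, df in canon.tables():
        out = df.copy()
        for col in DATE_COLUMNS[name]:
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(bundle / f"{name}.csv", index=False)
    meta = {
        "region": store.region,
        "icd_dialect": store.icd_dialect,
        "horizon": [store.horizon[0].isoformat(), store.horizon[1].isoformat()],
        "unavailable_services": list(store.unavailable_services),
    }
    (bundle / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
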