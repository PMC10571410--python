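"""Harmonized data model for regional healthcare-utilization (HCU) bundles.

A region's administrative data arrive as event tables — a patient registry,
outpatient mental-health contacts, hospital admissions, drug dispensations,
residential-facility stays, laboratory/specialist services and diagnosis
assignments — all linked by a pseudonymous patient identifier.  This module
defines the in-memory :class:`EventStore` holding those tables as pandas
DataFrames with a declared time horizon, plus validation of the linkage and
date invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterator

import pandas as pd

SEXES = ("F", "M")
SETTINGS = ("CMHC", "DC", "home")
WARD_TYPES = ("GHPW", "other")
PLANNED_FLAGS = ("planned", "unplanned")
DIAGNOSIS_SOURCES = ("MHIS", "hospital")
ICD_DIALECTS = ("icd10", "icd9cm")

#: table name -> required columns, in canonical order
SCHEMAS: dict[str, tuple[str, ...]] = {
    "patients": ("patient_id", "birth_date", "sex", "death_date"),
    "contacts": ("patient_id", "date", "setting", "intervention_type", "provider_role"),
    "admissions": (
        "patient_id",
        "ward_type",
        "admission_date",
        "discharge_date",
        "planned_flag",
        "diagnosis_codes",
    ),
    "dispensations": ("patient_id", "date", "atc_code", "n_ddd"),
    "residential": ("patient_id", "entry_date", "exit_date"),
    "lab_services": ("patient_id", "date", "service_code"),
    "diagnoses": ("patient_id", "date", "icd_code", "source"),
}

DATE_COLUMNS: dict[str, tuple[str, ...]] = {
    "patients": ("birth_date", "death_date"),
    "contacts": ("date",),
    "admissions": ("admission_date", "discharge_date"),
    "dispensations": ("date",),
    "residential": ("entry_date", "exit_date"),
    "lab_services": ("date",),
    "diagnoses": ("date",),
}

#: date columns that may legitimately be missing (open-ended / alive)
OPTIONAL_DATE_COLUMNS = {("patients", "death_date"), ("residential", "exit_date")}


class IntegrityError(ValueError):
    """A store violates a linkage or date invariant."""


def _empty_table(name: str) -> pd.DataFrame:
    cols = SCHEMAS[name]
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
    for c in DATE_COLUMNS[name]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    if name == "dispensations":
        df["n_ddd"] = pd.Series(dtype="float64")
    return df


@dataclass
class EventStore:
    """Linked event tables of one region.

    All tables are keyed by ``patient_id``; ``horizon`` is the inclusive
    first/last calendar date the extract covers, and ``icd_dialect`` declares
    which ICD vocabulary the region's diagnosis codes use (prefix matching
    makes most downstream logic dialect-agnostic).
    """

    region: str
    horizon: tuple[date, date]
    icd_dialect: str = "icd10"
    #: information the region's systems do not record (e.g. "psychoeducation",
    #: "home"); indicators relying on it are flagged unavailable downstream
    unavailable_services: tuple = ()
    patients: pd.DataFrame = field(default_factory=lambda: _empty_table("patients"))
    contacts: pd.DataFrame = field(default_factory=lambda: _empty_table("contacts"))
    admissions: pd.DataFrame = field(default_factory=lambda: _empty_table("admissions"))
    dispensations: pd.DataFrame = field(
        default_factory=lambda: _empty_table("dispensations")
    )
    residential: pd.DataFrame = field(default_factory=lambda: _empty_table("residential"))
    lab_services: pd.DataFrame = field(
        default_factory=lambda: _empty_table("lab_services")
    )
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty_table("diagnoses"))

    def tables(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for name in SCHEMAS:
            yield name, getattr(self, name)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def canonical(self) -> "EventStore":
        """Copy with every table sorted by all its columns (stable order for
        equality comparisons and byte-stable serialization)."""
        out = EventStore(
            region=self.region,
            horizon=self.horizon,
            icd_dialect=self.icd_dialect,
            unavailable_services=self.unavailable_services,
        )
        for name, df in self.tables():
            cols = list(SCHEMAS[name])
            sorted_df = (
                df[cols]
                .sort_values(cols, kind="mergesort", na_position="last")
                .reset_index(drop=True)
            )
            setattr(out, name, sorted_df)
        return out

    def equals(self, other: "EventStore") -> bool:
        if (self.region, self.horizon, self.icd_dialect, tuple(self.unavailable_services)) != (
            other.region,
            other.horizon,
            other.icd_dialect,
            tuple(other.unavailable_services),
        ):
            return False
        a, b = self.canonical(), other.canonical()
        return all(
            getattr(a, name).equals(getattr(b, name)) for name in SCHEMAS
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on the first violated invariant."""
        pats = self.patients
        if pats["patient_id"].duplicated().any():
            raise IntegrityError(f"{self.region}: duplicate patient_id in registry")
        if self.icd_dialect not in ICD_DIALECTS:
            raise IntegrityError(f"{self.region}: unknown ICD dialect {self.icd_dialect!r}")
        known = set(pats["patient_id"])
        dead = pats.dropna(subset=["death_date"])
        if (dead["death_date"] < dead["birth_date"]).any():
            raise IntegrityError(f"{self.region}: death_date before birth_date")
        lo, hi = (pd.Timestamp(self.horizon[0]), pd.Timestamp(self.horizon[1]))
        for name, df in self.tables():
            if name == "patients":
                continue
            unknown = set(df["patient_id"]) - known
            if unknown:
                raise IntegrityError(
                    f"{self.region}/{name}: {len(unknown)} events reference unknown patients"
                )
            for col in DATE_COLUMNS[name]:
                vals = df[col].dropna()
                if len(vals) and ((vals < lo).any() or (vals > hi).any()):
                    raise IntegrityError(
                        f"{self.region}/{name}.{col}: dates outside horizon"
                    )
        adm = self.admissions
        if len(adm) and (adm["discharge_date"] < adm["admission_date"]).any():
            raise IntegrityError(f"{self.region}: discharge before admission")
        res = self.residential.dropna(subset=["exit_date"])
        if len(res) and (res["exit_date"] < res["entry_date"]).any():
            raise IntegrityError(f"{self.region}: residential exit before entry")
        disp = self.dispensations
        if len(disp) and (disp["n_ddd"] <= 0).any():
            raise IntegrityError(f"{self.region}: non-positive n_ddd")
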