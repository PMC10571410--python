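"""Shared fixtures: generated regions and a factory for handcrafted stores."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from mhqi import EventStore, RegionScenario, generate_multiregion, generate_region

HORIZON = (date(2013, 1, 1), date(2016, 12, 31))


def make_store(
    patients=(),
    contacts=(),
    admissions=(),
    dispensations=(),
    residential=(),
    lab_services=(),
    diagnoses=(),
    region="handmade",
    horizon=HORIZON,
    icd_dialect="icd10",
    unavailable_services=(),
) -> EventStore:
    """Build a small store from plain tuples.

    patients: (pid, birth, sex, death); contacts: (pid, date, setting, type);
    admissions: (pid, ward, adm, disch, planned); dispensations:
    (pid, date, atc, ddd); residential: (pid, entry, exit); lab_services:
    (pid, date, code); diagnoses: (pid, date, icd, source).
    """
    store = EventStore(
        region=region,
        horizon=horizon,
        icd_dialect=icd_dialect,
        unavailable_services=tuple(unavailable_services),
    )

    def frame(rows, cols, date_cols):
        df = pd.DataFrame(list(rows), columns=cols)
        for c in date_cols:
            df[c] = pd.to_datetime(df[c])
        return df

    if patients:
        store.patients = frame(patients, ["patient_id", "birth_date", "sex", "death_date"], ["birth_date", "death_date"])
    if contacts:
        rows = [(*c, None) for c in contacts]
        store.contacts = frame(rows, ["patient_id", "date", "setting", "intervention_type", "provider_role"], ["date"])
    if admissions:
        rows = [(*a, "") for a in admissions]
        store.admissions = frame(rows, ["patient_id", "ward_type", "admission_date", "discharge_date", "planned_flag", "diagnosis_codes"], ["admission_date", "discharge_date"])
    if dispensations:
        store.dispensations = frame(dispensations, ["patient_id", "date", "atc_code", "n_ddd"], ["date"])
    if residential:
        store.residential = frame(residential, ["patient_id", "entry_date", "exit_date"], ["entry_date", "exit_date"])
    if lab_services:
        store.lab_services = frame(lab_services, ["patient_id", "date", "service_code"], ["date"])
    if diagnoses:
        store.diagnoses = frame(diagnoses, ["patient_id", "date", "icd_code", "source"], ["date"])
    return store


@pytest.fixture(scope="session")
def small_region():
    """One generated region, ~600 cohort patients, all services available."""
    scenario = RegionScenario(region="alpha", n_prevalent=600, n_newly=80, seed=11)
    return generate_region(scenario)


@pytest.fixture(scope="session")
def small_multiregion():
    """Three generated regions with heterogeneous parameters, one using
    ICD-9-CM coding and regionally unavailable services."""
    scenarios = [
        RegionScenario(region="alpha", n_prevalent=500, n_newly=60, seed=3),
        RegionScenario(
            region="beta",
            n_prevalent=350,
            n_newly=45,
            seed=3,
            icd_dialect="icd9cm",
            p_ghpw_admission=0.09,
            p_contact=0.98,
            p_antipsychotic=0.35,
            unavailable_services=("home",),
        ),
        RegionScenario(
            region="gamma",
            n_prevalent=200,
            n_newly=25,
            seed=3,
            p_contact=0.80,
            p_ghpw_admission=0.16,
            p_community_persistent=0.35,
            unavailable_services=("psychoeducation",),
        ),
    ]
    return generate_multiregion(scenarios)
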