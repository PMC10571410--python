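"""Cohort selection: prevalent patients and the newly-taken-in-care subset.

The prevalent cohort of a recruitment year contains patients aged 18-65 who
carry a personality-disorder diagnosis and had at least one contact with a
department of mental health (DMH) that year; the date of the first such
contact is the index date and follow-up runs one year from it.  "Contact
with a DMH" is read broadly — an outpatient contact, a psychiatric-ward
(GHPW) admission or a residential-facility entry — since a fraction of
patients is reached only through hospital or residential care.

The newly-taken-in-care sub-cohort applies an incident-user washout: a
prevalent member is excluded if, before the index date, they ever received a
personality-disorder diagnosis or a GHPW admission, or if the two-year
lookback contains at least two *consecutive* psychotropic dispensations
(consecutive in the treatment-episode sense: the interval from the end of
supply of one to the start of the next is under 90 days).  The remaining
members are restricted to ages 18-40.  Every excluded member is accounted
for by one exclusion trace per failed criterion.
"""

from __future__ import annotations

import logging
import math
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .coding import PSYCHOTROPIC, CodingMaps, DEFAULT_MAPS
from .episodes import DEFAULT_GAP_DAYS
from .model import EventStore, IntegrityError

log = logging.getLogger(__name__)

FOLLOW_UP_DAYS = 365
PREVALENT_AGE = (18, 65)
NEWLY_AGE = (18, 40)
LOOKBACK_DAYS = 730

MEMBER_COLUMNS = (
    "patient_id",
    "cohort",
    "index_date",
    "follow_up_end",
    "age_at_index",
    "sex",
    "death_date",
    "person_years",
)


def age_at(birth: date, on: date) -> int:
    """Completed years of age on a given date."""
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def accrue_person_years(index: date, follow_up_end: date, death: date | None) -> float:
    """Person-years from index to the earlier of follow-up end and death.

    A patient observed for the whole window contributes exactly 1.0; a death
    inside the window contributes the elapsed days over 365.25.
    """
    if death is not None and death <= index:
        raise IntegrityError(f"death {death} not after index {index}")
    if death is None or death >= follow_up_end:
        return 1.0
    return (death - index).days / 365.25


def _pd_diagnosis_dates(store: EventStore, maps: CodingMaps) -> pd.DataFrame:
    """All (patient_id, date) personality-disorder diagnosis assignments,
    from the diagnosis table and from admission discharge codes."""
    diag = store.diagnoses
    mask = diag["icd_code"].map(lambda c: maps.is_personality_disorder(str(c))).astype(bool)
    hits = diag[mask]
    frames = [hits[["patient_id", "date"]]]
    adm = store.admissions
    if len(adm):
        codes = adm["diagnosis_codes"].fillna("")
        has_pd = codes.map(
            lambda c: any(maps.is_personality_disorder(x) for x in str(c).split(";") if x)
        ).astype(bool)
        sub = adm[has_pd][["patient_id", "discharge_date"]].rename(
            columns={"discharge_date": "date"}
        )
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def _dmh_contact_events(store: EventStore) -> pd.DataFrame:
    """All DMH-contact events as (patient_id, date, priority); priority
    breaks same-day ties: contact(0) > admission(1) > residential(2)."""
    parts = []
    if len(store.contacts):
        c = store.contacts[["patient_id", "date"]].copy()
        c["priority"] = 0
        parts.append(c)
    adm = store.admissions
    adm = adm[adm["ward_type"] == "GHPW"]
    if len(adm):
        a = adm[["patient_id", "admission_date"]].rename(columns={"admission_date": "date"})
        a["priority"] = 1
        parts.append(a)
    if len(store.residential):
        r = store.residential[["patient_id", "entry_date"]].rename(columns={"entry_date": "date"})
        r["priority"] = 2
        parts.append(r)
    if not parts:
        return pd.DataFrame(columns=["patient_id", "date", "priority"])
    return pd.concat(parts, ignore_index=True)


def select_prevalent(
    store: EventStore,
    recruitment_year: int,
    maps: CodingMaps = DEFAULT_MAPS,
) -> pd.DataFrame:
    """Build the prevalent cohort for one recruitment year.

    Returns one row per member with index date, follow-up end, completed age
    at index and accrued person-years (columns ``MEMBER_COLUMNS``).
    """
    y0 = pd.Timestamp(date(recruitment_year, 1, 1))
    y1 = pd.Timestamp(date(recruitment_year, 12, 31))

    events = _dmh_contact_events(store)
    events = events[(events["date"] >= y0) & (events["date"] <= y1)]
    if events.empty:
        return pd.DataFrame(columns=MEMBER_COLUMNS)
    first = (
        events.sort_values(["patient_id", "date", "priority"])
        .groupby("patient_id", as_index=False)
        .first()[["patient_id", "date"]]
        .rename(columns={"date": "index_date"})
    )

    diags = _pd_diagnosis_dates(store, maps)
    diags = diags[(diags["date"] >= y0) & (diags["date"] <= y1)]
    qualified = set(diags["patient_id"])
    first = first[first["patient_id"].isin(qualified)]

    pats = store.patients.set_index("patient_id")
    rows = []
    for pid, idx in zip(first["patient_id"], first["index_date"]):
        birth = pats.at[pid, "birth_date"]
        a = age_at(birth.date(), idx.date())
        if not PREVALENT_AGE[0] <= a <= PREVALENT_AGE[1]:
            continue
        death = pats.at[pid, "death_date"]
        death_d = None if pd.isna(death) else death.date()
        fu_end = idx.date() + timedelta(days=FOLLOW_UP_DAYS)
        rows.append(
            {
                "patient_id": pid,
                "cohort": "prevalent",
                "index_date": idx.date(),
                "follow_up_end": fu_end,
                "age_at_index": a,
                "sex": pats.at[pid, "sex"],
                "death_date": death_d,
                "person_years": accrue_person_years(idx.date(), fu_end, death_d),
            }
        )
    return pd.DataFrame(rows, columns=MEMBER_COLUMNS)


def _consecutive_psychotropics(
    disp: pd.DataFrame, gap_days: int
) -> bool:
    """True when any adjacent pair of dispensations is consecutive (interval
    from end of supply of the first to start of the second under the gap)."""
    days = disp["date"].map(pd.Timestamp.toordinal).to_numpy()
    ddd = disp["n_ddd"].to_numpy(dtype=float)
    order = np.argsort(days, kind="stable")
    days, ddd = days[order], ddd[order]
    for i in range(len(days) - 1):
        end_of_supply = days[i] + math.ceil(ddd[i]) - 1
        if days[i + 1] - end_of_supply < gap_days:
            return True
    return False


def select_newly_taken_in_care(
    store: EventStore,
    prevalent: pd.DataFrame,
    maps: CodingMaps = DEFAULT_MAPS,
    gap_days: int = DEFAULT_GAP_DAYS,
    lookback_days: int = LOOKBACK_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the incident-user washout to the prevalent cohort.

    Returns ``(newly, traces)``: the newly-taken-in-care members (cohort
    label replaced) and one trace row per (patient, exclusion reason).
    A lookback window extending before the data horizon is logged; the
    patient is retained unless a disqualifying event is actually observed.
    """
    if prevalent.empty:
        return prevalent.copy(), pd.DataFrame(
            columns=["patient_id", "exclusion_reason", "evidence"]
        )
    idx_by_pid = dict(zip(prevalent["patient_id"], prevalent["index_date"]))
    member_ids = set(idx_by_pid)

    diags = _pd_diagnosis_dates(store, maps)
    diags = diags[diags["patient_id"].isin(member_ids)]
    prior_diag: dict[str, date] = {}
    for pid, d in zip(diags["patient_id"], diags["date"]):
        if d.date() < idx_by_pid[pid]:
            if pid not in prior_diag or d.date() < prior_diag[pid]:
                prior_diag[pid] = d.date()

    adm = store.admissions
    adm = adm[(adm["ward_type"] == "GHPW") & adm["patient_id"].isin(member_ids)]
    prior_adm: dict[str, date] = {}
    for pid, d in zip(adm["patient_id"], adm["admission_date"]):
        if d.date() < idx_by_pid[pid]:
            if pid not in prior_adm or d.date() < prior_adm[pid]:
                prior_adm[pid] = d.date()

    disp = store.dispensations
    disp = disp[disp["patient_id"].isin(member_ids)]
    if len(disp):
        psycho = disp[
            disp["atc_code"]
            .map(lambda a: PSYCHOTROPIC in maps.drug_memberships(str(a)))
            .astype(bool)
        ]
    else:
        psycho = disp
    prior_rx: set[str] = set()
    horizon_start = pd.Timestamp(store.horizon[0])
    n_censored = 0
    for pid, grp in psycho.groupby("patient_id"):
        idx = pd.Timestamp(idx_by_pid[pid])
        lb0 = idx - pd.Timedelta(days=lookback_days)
        if lb0 < horizon_start:
            n_censored += 1
        in_lb = grp[(grp["date"] >= lb0) & (grp["date"] < idx)]
        if len(in_lb) >= 2 and _consecutive_psychotropics(in_lb, gap_days):
            prior_rx.add(pid)
    if n_censored:
        log.warning(
            "%d members have a lookback window extending before the data horizon; "
            "retained unless a disqualifying event was observed",
            n_censored,
        )

    traces = []
    keep = []
    for _, row in prevalent.iterrows():
        pid = row["patient_id"]
        reasons = []
        if pid in prior_diag:
            reasons.append(("prior_diagnosis", f"diagnosis on {prior_diag[pid]}"))
        if pid in prior_adm:
            reasons.append(("prior_ghpw_admission", f"admission on {prior_adm[pid]}"))
        if pid in prior_rx:
            reasons.append(("prior_psychotropic_use", "consecutive dispensations in lookback"))
        if not NEWLY_AGE[0] <= row["age_at_index"] <= NEWLY_AGE[1]:
            reasons.append(("age_out_of_range", f"age {row['age_at_index']} at index"))
        if reasons:
            for r, ev in reasons:
                traces.append({"patient_id": pid, "exclusion_reason": r, "evidence": ev})
        else:
            keep.append(pid)

    newly = prevalent[prevalent["patient_id"].isin(keep)].copy()
    newly["cohort"] = "newly_taken_in_care"
    return newly.reset_index(drop=True), pd.DataFrame(
        traces, columns=["patient_id", "exclusion_reason", "evidence"]
    )
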