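"""The clinical-indicator catalogue: 33 measures per region and cohort.

The catalogue covers three quality domains — accessibility/appropriateness
(1-23), continuity (24-28) and safety (29-33) of mental healthcare — each
indicator being either a proportion (numerator/denominator counts), a median
number of events per person-year among patients with at least one qualifying
event, or a standardized mortality ratio.  Conventions that matter:

* "treated with class X" means at least one dispensation of the class during
  follow-up (no minimum-exposure qualifier);
* intensity medians are computed among users (patients with >= 1 qualifying
  event), not over the whole cohort;
* readmission indicators use the admission as the statistical unit: the
  denominator is all psychiatric-ward admissions during follow-up, and an
  admission counts in the numerator when it is unplanned and starts within
  7/30 days of the patient's previous discharge;
* discharge follow-up indicators (26-28) only count discharges whose 14-day
  observation window fits entirely inside follow-up;
* an indicator that a region's information systems cannot inform (e.g.
  psychoeducation recording, home-care recording) is flagged unavailable and
  later excluded from that region's contribution to pooled values.

Everything is computed from a per-patient feature table
(:func:`patient_features`) so that indicator definitions stay one-liners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .coding import (
    ANTIDEPRESSANT,
    ANTIPSYCHOTIC,
    LAMOTRIGINE,
    LITHIUM,
    MOOD_STABILIZER,
    VALPROATE_CARBAMAZEPINE,
    CodingMaps,
    DEFAULT_MAPS,
)
from .episodes import community_persistence, drug_persistence
from .model import EventStore
from .pooling import compute_smr
from .synthetic import DEFAULT_MORTALITY

DOMAIN_ACCESS = "accessibility_appropriateness"
DOMAIN_CONTINUITY = "continuity"
DOMAIN_SAFETY = "safety"

_TYPE_COUNT_COLS = {
    "psychiatric_visit": "n_psychiatric_visits",
    "standardized_assessment": "n_assessments",
    "psychosocial_intervention": "n_psychosocial",
    "psychoeducation": "n_psychoeducation",
    "psychotherapy": "n_psychotherapy",
    "family_intervention": "n_family",
}


def _day_array(series: pd.Series) -> np.ndarray:
    """Datetime series -> integer days since epoch (NaT -> INT_MIN)."""
    return series.to_numpy().astype("datetime64[D]").astype("int64")


_NAT_DAY = np.datetime64("NaT").astype("datetime64[D]").astype("int64")


def _bucket(df: pd.DataFrame, *cols) -> dict:
    """patient_id -> list of column tuples, dates as epoch-day ints."""
    out: dict = {}
    if not len(df):
        return out
    arrays = []
    for c in cols:
        if np.issubdtype(df[c].dtype, np.datetime64):
            arrays.append(_day_array(df[c]))
        else:
            arrays.append(df[c].to_numpy())
    for pid, *vals in zip(df["patient_id"].to_numpy(), *arrays):
        out.setdefault(pid, []).append(tuple(vals))
    return out


def patient_features(
    store: EventStore,
    members: pd.DataFrame,
    maps: CodingMaps = DEFAULT_MAPS,
    gap_days: int = 90,
) -> pd.DataFrame:
    """Per-member follow-up features driving every indicator.

    The follow-up window of a member runs from the index date to the earlier
    of index + 365 days and death; all event counts, exposure flags and
    persistence verdicts refer to that window.  Day offsets are relative to
    the index date.
    """
    contacts_by = _bucket(store.contacts, "date", "setting", "intervention_type")
    adms_by = _bucket(
        store.admissions[store.admissions["ward_type"] == "GHPW"],
        "admission_date",
        "discharge_date",
        "planned_flag",
    )
    disp_by = _bucket(store.dispensations, "date", "atc_code", "n_ddd")
    res_by = _bucket(store.residential, "entry_date", "exit_date")
    labs_by = _bucket(store.lab_services, "date", "service_code")
    membership_cache: dict[str, frozenset] = {}

    index_days = _day_array(pd.to_datetime(members["index_date"]))
    death_days = _day_array(pd.to_datetime(members["death_date"]))

    rows = []
    for (_, m), idx_day, death_day in zip(members.iterrows(), index_days, death_days):
        pid = m["patient_id"]
        has_death = death_day != _NAT_DAY
        w1 = 365 if not has_death else min(365, int(death_day - idx_day))

        # contacts ----------------------------------------------------------
        type_counts = {col: 0 for col in _TYPE_COUNT_COLS.values()}
        n_cmhc = n_cmhc_dc = 0
        contact_events: list[tuple[int, str, str]] = []
        for day, setting, itype in contacts_by.get(pid, ()):
            d = int(day - idx_day)
            if not 0 <= d < w1:
                continue
            contact_events.append((d, setting, itype))
            if setting == "CMHC":
                n_cmhc += 1
            if setting in ("CMHC", "DC"):
                n_cmhc_dc += 1
            col = _TYPE_COUNT_COLS.get(itype)
            if col:
                type_counts[col] += 1

        # admissions --------------------------------------------------------
        adm_intervals: list[tuple[int, int, str]] = []
        for adm_d, dis_d, planned in sorted(adms_by.get(pid, ())):
            r0 = int(adm_d - idx_day)
            if 0 <= r0 < w1:
                r1 = int(dis_d - idx_day)
                if adm_intervals and r0 < adm_intervals[-1][1]:
                    # overlapping records: merge into one stay
                    p0, p1, fl = adm_intervals[-1]
                    adm_intervals[-1] = (p0, max(p1, r1), fl)
                    continue
                adm_intervals.append((r0, r1, planned))
        ghpw_days = sum(d1 - d0 for d0, d1, _ in adm_intervals)
        n_long = sum(1 for d0, d1, _ in adm_intervals if d1 - d0 > 30)
        n_re7 = n_re30 = 0
        for k in range(1, len(adm_intervals)):
            gap = adm_intervals[k][0] - adm_intervals[k - 1][1]
            if adm_intervals[k][2] == "unplanned":
                if gap <= 7:
                    n_re7 += 1
                if gap <= 30:
                    n_re30 += 1
        n_obs = n_fa = n_fp = n_fh = 0
        for _, dis, _pl in adm_intervals:
            if dis + 14 >= w1:
                continue
            n_obs += 1
            win = [ev for ev in contact_events if dis < ev[0] <= dis + 14]
            if win:
                n_fa += 1
            if any(ev[2] == "psychiatric_visit" for ev in win):
                n_fp += 1
            if any(ev[1] == "home" for ev in win):
                n_fh += 1

        # residential -------------------------------------------------------
        res_intervals: list[tuple[int, int]] = []
        for e_d, x_d in res_by.get(pid, ()):
            r0 = int(e_d - idx_day)
            if not 0 <= r0 < w1:
                continue
            r1 = w1 if x_d == _NAT_DAY else min(int(x_d - idx_day), w1)
            res_intervals.append((r0, max(r1, r0)))
        res_days = sum(r1 - r0 for r0, r1 in res_intervals)

        # dispensations -----------------------------------------------------
        by_class: dict[str, list[tuple[int, float]]] = {}
        treated: dict[str, bool] = {}
        for dd, atc, q in disp_by.get(pid, ()):
            memb = membership_cache.get(atc)
            if memb is None:
                memb = maps.drug_memberships(str(atc))
                membership_cache[atc] = memb
            for cls in memb:
                by_class.setdefault(cls, []).append((int(dd - idx_day), float(q)))
        for cls in (
            ANTIPSYCHOTIC,
            LITHIUM,
            VALPROATE_CARBAMAZEPINE,
            LAMOTRIGINE,
            MOOD_STABILIZER,
            ANTIDEPRESSANT,
        ):
            treated[cls] = any(0 <= day < w1 for day, _ in by_class.get(cls, ()))

        # persistence -------------------------------------------------------
        bridge = [(d0, d1 - 1) for d0, d1, _ in adm_intervals if d1 > d0]
        bridge += [(r0, r1 - 1) for r0, r1 in res_intervals if r1 > r0]
        cmhc_dc_days = [ev[0] for ev in contact_events if ev[1] in ("CMHC", "DC")]
        comm = community_persistence(cmhc_dc_days, (0, w1), bridge, gap_days=gap_days)
        ms_verdict = drug_persistence(
            by_class.get(MOOD_STABILIZER, ()), (0, w1), bridge, gap_days=gap_days
        )

        # monitoring --------------------------------------------------------
        codes_in_w = {
            code for day, code in labs_by.get(pid, ()) if 0 <= day - idx_day < w1
        }

        def panel_done(cls: str) -> Optional[bool]:
            if not treated[cls]:
                return None
            panel = maps.monitoring_panel(cls)
            return bool(panel) and panel <= codes_in_w

        rows.append(
            {
                "patient_id": pid,
                "person_years": m["person_years"],
                "age_at_index": m["age_at_index"],
                "sex": m["sex"],
                "died": has_death and w1 < 365,
                "n_contacts_cmhc_dc": n_cmhc_dc,
                "n_contacts_cmhc": n_cmhc,
                **type_counts,
                "treated_antipsychotic": treated[ANTIPSYCHOTIC],
                "treated_lithium": treated[LITHIUM],
                "treated_vpa_cbz": treated[VALPROATE_CARBAMAZEPINE],
                "treated_lamotrigine": treated[LAMOTRIGINE],
                "treated_mood_stabilizer": treated[MOOD_STABILIZER],
                "treated_antidepressant": treated[ANTIDEPRESSANT],
                "has_residential": len(res_intervals) > 0,
                "residential_days": res_days,
                "has_ghpw": len(adm_intervals) > 0,
                "ghpw_days": ghpw_days,
                "n_admissions": len(adm_intervals),
                "n_long_admissions": n_long,
                "n_readmissions_7d": n_re7,
                "n_readmissions_30d": n_re30,
                "n_discharges_observable": n_obs,
                "n_discharges_followed_any": n_fa,
                "n_discharges_followed_psych": n_fp,
                "n_discharges_followed_home": n_fh,
                "community_persistent": comm.persistent,
                "ms_persistent": None if ms_verdict is None else ms_verdict.persistent,
                "monitored_antipsychotic": panel_done(ANTIPSYCHOTIC),
                "monitored_lithium": panel_done(LITHIUM),
                "monitored_vpa_cbz": panel_done(VALPROATE_CARBAMAZEPINE),
                "monitored_lamotrigine": panel_done(LAMOTRIGINE),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# catalogue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndicatorDefinition:
    id: str
    label: str
    domain: str
    kind: str  # proportion | median_per_py | smr
    #: feature-table reduction: proportions -> (numerator, denominator),
    #: medians -> per-patient rate sample
    reduce: Callable[[pd.DataFrame], object]
    #: service whose regional absence makes the indicator unavailable
    requires_service: Optional[str] = None


def _prop(flag: str) -> Callable:
    return lambda f: (int(f[flag].sum()), len(f))


def _prop_among(flag: str, among: str) -> Callable:
    def reduce(f: pd.DataFrame):
        den = f[f[among].map(bool)]
        return int(den[flag].map(lambda v: bool(v)).sum()), len(den)

    return reduce


def _count_prop(num_col: str, den_col: str) -> Callable:
    return lambda f: (int(f[num_col].sum()), int(f[den_col].sum()))


def _rate_sample(count_col: str) -> Callable:
    def reduce(f: pd.DataFrame) -> np.ndarray:
        users = f[f[count_col] > 0]
        return (users[count_col] / users["person_years"]).to_numpy(dtype=float)

    return reduce


def _has(count_col: str) -> Callable:
    return lambda f: (int((f[count_col] > 0).sum()), len(f))


INDICATORS: tuple[IndicatorDefinition, ...] = (
    IndicatorDefinition("1", "Patients with at least one outpatient contact in CMHCs or DCs", DOMAIN_ACCESS, "proportion", _has("n_contacts_cmhc_dc")),
    IndicatorDefinition("2", "Median number of outpatient contacts in CMHCs (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("n_contacts_cmhc")),
    IndicatorDefinition("3", "Patients with at least one psychiatric visit", DOMAIN_ACCESS, "proportion", _has("n_psychiatric_visits")),
    IndicatorDefinition("4", "Median number of outpatient psychiatric visits (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("n_psychiatric_visits")),
    IndicatorDefinition("5", "Patients with at least one standardized assessment using tests", DOMAIN_ACCESS, "proportion", _has("n_assessments")),
    IndicatorDefinition("6", "Median number of standardized assessments using tests (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("n_assessments")),
    IndicatorDefinition("7", "Patients treated with at least one psychosocial intervention in CMHCs", DOMAIN_ACCESS, "proportion", _has("n_psychosocial")),
    IndicatorDefinition("8", "Median number of psychosocial interventions in CMHCs (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("n_psychosocial")),
    IndicatorDefinition("9", "Patients treated with at least one psychoeducation session", DOMAIN_ACCESS, "proportion", _has("n_psychoeducation"), "psychoeducation"),
    IndicatorDefinition("10", "Median number of psychoeducation sessions (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("n_psychoeducation"), "psychoeducation"),
    IndicatorDefinition("11", "Patients treated with at least one psychotherapy session", DOMAIN_ACCESS, "proportion", _has("n_psychotherapy")),
    IndicatorDefinition("12", "Median number of psychotherapy sessions (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("n_psychotherapy")),
    IndicatorDefinition("13", "Median number of interventions addressed to family members (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("n_family")),
    IndicatorDefinition("14", "Patients treated with antipsychotic agents", DOMAIN_ACCESS, "proportion", _prop("treated_antipsychotic")),
    IndicatorDefinition("15", "Patients treated with Mood Stabilizers", DOMAIN_ACCESS, "proportion", _prop("treated_mood_stabilizer")),
    IndicatorDefinition("15a", "Patients treated with Lithium", DOMAIN_ACCESS, "proportion", _prop("treated_lithium")),
    IndicatorDefinition("15b", "Patients treated with Valproic acid, Carbamazepine", DOMAIN_ACCESS, "proportion", _prop("treated_vpa_cbz")),
    IndicatorDefinition("16", "Patients treated with Antidepressant agents", DOMAIN_ACCESS, "proportion", _prop("treated_antidepressant")),
    IndicatorDefinition("17", "Patients with at least one admission in residential facilities", DOMAIN_ACCESS, "proportion", _prop("has_residential")),
    IndicatorDefinition("18", "Median number of days spent in residential facilities (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("residential_days")),
    IndicatorDefinition("19", "Patients with at least one admission in GHPW", DOMAIN_ACCESS, "proportion", _prop("has_ghpw")),
    IndicatorDefinition("20", "Median number of days spent in GHPW (per PY)", DOMAIN_ACCESS, "median_per_py", _rate_sample("ghpw_days")),
    IndicatorDefinition("21", "Admissions with a length of stay in GHPW higher than 30 days", DOMAIN_ACCESS, "proportion", _count_prop("n_long_admissions", "n_admissions")),
    IndicatorDefinition("22", "Unplanned re-admissions in GHPW within 7 days", DOMAIN_ACCESS, "proportion", _count_prop("n_readmissions_7d", "n_admissions")),
    IndicatorDefinition("23", "Unplanned re-admissions in GHPW within 30 days", DOMAIN_ACCESS, "proportion", _count_prop("n_readmissions_30d", "n_admissions")),
    IndicatorDefinition("24", "Patients with continuous community care", DOMAIN_CONTINUITY, "proportion", _prop("community_persistent")),
    IndicatorDefinition("25", "Patients persistent with Mood stabilizers therapy", DOMAIN_CONTINUITY, "proportion", _prop_among("ms_persistent", "treated_mood_stabilizer")),
    IndicatorDefinition("26", "GHPW discharges followed by any outpatient contact within 14 days", DOMAIN_CONTINUITY, "proportion", _count_prop("n_discharges_followed_any", "n_discharges_observable")),
    IndicatorDefinition("27", "GHPW discharges followed by an outpatient psychiatric visit within 14 days", DOMAIN_CONTINUITY, "proportion", _count_prop("n_discharges_followed_psych", "n_discharges_observable")),
    IndicatorDefinition("28", "GHPW discharges followed by home care within 14 days", DOMAIN_CONTINUITY, "proportion", _count_prop("n_discharges_followed_home", "n_discharges_observable"), "home"),
    IndicatorDefinition("29", "Patients monitored for hyperglycaemia and hyperlipidaemia (antipsychotic-treated)", DOMAIN_SAFETY, "proportion", _prop_among("monitored_antipsychotic", "treated_antipsychotic")),
    IndicatorDefinition("30", "Patients monitored with Lithaemia (lithium-treated)", DOMAIN_SAFETY, "proportion", _prop_among("monitored_lithium", "treated_lithium")),
    IndicatorDefinition("31", "Patients with a complete set of clinical controls (valproate/carbamazepine-treated)", DOMAIN_SAFETY, "proportion", _prop_among("monitored_vpa_cbz", "treated_vpa_cbz")),
    IndicatorDefinition("32", "Patients with a complete set of clinical controls (lamotrigine-treated)", DOMAIN_SAFETY, "proportion", _prop_among("monitored_lamotrigine", "treated_lamotrigine")),
    IndicatorDefinition("33", "Mortality (SMR) and relative 95% CI", DOMAIN_SAFETY, "smr", lambda f: f),
)

INDICATOR_IDS = tuple(d.id for d in INDICATORS)


def median_per_py(rates: np.ndarray) -> float:
    """Median per-person-year rate among users (even size: mean of the
    central pair); NaN for an empty pool."""
    if len(rates) == 0:
        return float("nan")
    return float(np.median(rates))


def expected_deaths(
    features: pd.DataFrame, reference_mortality: dict = DEFAULT_MORTALITY
) -> float:
    """Expected deaths from reference age/sex rates applied to person-years."""
    bands = np.where(features["age_at_index"] <= 40, "18-40", "41-65")
    rates = np.array(
        [reference_mortality[(b, s)] for b, s in zip(bands, features["sex"])]
    )
    return float((rates * features["person_years"].to_numpy()).sum())


def compute_indicators(
    store: EventStore,
    members: pd.DataFrame,
    cohort: str,
    maps: CodingMaps = DEFAULT_MAPS,
    reference_mortality: dict = DEFAULT_MORTALITY,
    gap_days: int = 90,
    only: Optional[set] = None,
    features: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict]:
    """Compute the indicator grid for one region and cohort.

    Returns ``(results, samples)``: one row per indicator with numerator,
    denominator, value and availability, plus the per-patient rate samples
    backing each median (needed for between-region homogeneity tests).
    ``only`` restricts computation to a subset of indicator ids.
    """
    if features is None:
        features = patient_features(store, members, maps, gap_days=gap_days)
    unavailable = set(store.unavailable_services)
    rows, samples = [], {}
    for defn in INDICATORS:
        if only is not None and defn.id not in only:
            continue
        available = defn.requires_service not in unavailable
        base = {
            "indicator_id": defn.id,
            "label": defn.label,
            "domain": defn.domain,
            "kind": defn.kind,
            "region": store.region,
            "cohort": cohort,
            "n_available": available,
            "numerator": np.nan,
            "denominator": np.nan,
            "value": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
        if not available or len(features) == 0:
            rows.append(base)
            continue
        if defn.kind == "proportion":
            num, den = defn.reduce(features)
            base.update(
                numerator=num,
                denominator=den,
                value=100.0 * num / den if den else np.nan,
            )
        elif defn.kind == "median_per_py":
            sample = defn.reduce(features)
            samples[defn.id] = sample
            base.update(denominator=len(sample), value=median_per_py(sample))
        else:  # smr
            observed = int(features["died"].sum())
            expected = expected_deaths(features, reference_mortality)
            res = compute_smr(observed, expected)
            base.update(
                numerator=observed,
                denominator=expected,
                value=res.smr,
                ci_low=res.ci95[0],
                ci_high=res.ci95[1],
            )
        rows.append(base)
    return pd.DataFrame(rows), samples
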