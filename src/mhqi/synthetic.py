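"""Synthetic multi-region healthcare-utilization bundles with known truth.

The regional databases this pipeline is designed for are confidential, so
development and testing run on synthetic bundles that emulate their
statistical structure: per-patient event streams over a recruitment year
plus one year of follow-up and a two-year lookback, with region-specific
contact rates, prescription patterns, admission/readmission dynamics and
mortality.  Every generated region comes with a *ground-truth ledger* — one
row per cohort patient recording their true cohort label, exclusion reasons,
person-years and realized per-indicator flags/counts — so that pipeline
estimates can be compared with known truth instead of eyeballed.

Generative model (deliberately the simplest structure that exercises every
indicator):

* cohort membership is drawn per population stratum (age band x sex) from a
  treated-prevalence rate, or fixed via ``n_prevalent``;
* outpatient contacts follow a per-patient Poisson count placed uniformly in
  the follow-up window, with an explicit persistent/non-persistent contact
  pattern controlling gaps in community care;
* each intervention type (psychiatric visit, standardized assessment, ...)
  is a per-patient Bernoulli with a Poisson intensity for repeat sessions;
* drug exposure per class is a Bernoulli "treated" flag with monthly refills
  for persistent patients and an early stop otherwise (geometric-like
  inter-fill gaps);
* hospital stay lengths are lognormal; readmissions follow configured 7/30
  day probabilities; residential stays are lognormal and may remain open;
* deaths are drawn from baseline age/sex mortality scaled by a true
  standardized-mortality multiplier, so SMR estimation is recoverable.

Ledger flags are computed *post hoc* from the events actually emitted (a
death can truncate a planned event stream), using compact day-grid routines
that are independent of the interval arithmetic in :mod:`mhqi.episodes`.
Generation is fully deterministic given ``(scenario, seed)``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import EventStore

AGE_BANDS = ("18-40", "41-65")

#: baseline all-cause mortality per person-year, adult general population
DEFAULT_MORTALITY = {
    ("18-40", "F"): 0.0003,
    ("18-40", "M"): 0.0008,
    ("41-65", "F"): 0.0020,
    ("41-65", "M"): 0.0038,
}

#: adult population composition: (age band, sex) -> share
DEFAULT_POPULATION_SHARES = {
    ("18-40", "F"): 0.22,
    ("18-40", "M"): 0.23,
    ("41-65", "F"): 0.28,
    ("41-65", "M"): 0.27,
}

_ATC_BY_CLASS = {
    "antipsychotic": ("N05AH04", "N05AX08", "N05AA01", "N05AX12"),
    "lithium": ("N05AN01",),
    "valproate_carbamazepine": ("N03AG01", "N03AF01"),
    "lamotrigine": ("N03AX09",),
    "other_mood_stabilizer": ("N03AX16", "N03AE01"),
    "antidepressant": ("N06AB06", "N06AX11", "N06AA04"),
}

_PD_CODES = {
    "icd10": ("F60.3", "F60.0", "F60.8", "F61"),
    "icd9cm": ("301.83", "301.9", "301.0", "301.50"),
}

_MONITOR_PANELS = {
    "antipsychotic": ("glycaemia", "lipid_panel"),
    "lithium": ("lithaemia", "electrolytes"),
    "valproate_carbamazepine": ("blood_count", "transaminases"),
    "lamotrigine": ("blood_count",),
}

EXCLUSION_REASONS = (
    "prior_diagnosis",
    "prior_ghpw_admission",
    "prior_psychotropic_use",
    "age_out_of_range",
)


class ConfigurationError(ValueError):
    """An invalid scenario parameter (probability outside [0, 1], ...)."""


@dataclass
class RegionScenario:
    """Ground-truth parameters of one synthetic region.

    Probabilities prefixed ``p_`` are per-cohort-patient marginals for the
    matching indicator (e.g. ``p_ghpw_admission`` is the true share of the
    cohort with at least one psychiatric-ward admission during follow-up);
    ``*_rate`` values are mean events per person-year among users.
    """

    region: str
    recruitment_year: int = 2015
    icd_dialect: str = "icd10"
    seed: int = 0

    # population and cohort sizes
    n_adults: int = 200_000
    population_shares: dict = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_SHARES)
    )
    prevalence_per_10k: float = 17.6
    incidence_per_10k: float = 4.1  # ages 18-40, newly-taken-in-care
    n_prevalent: Optional[int] = None  # fixed cohort size override
    n_newly: Optional[int] = None
    n_background: int = 20  # registered patients with contacts but no qualifying diagnosis

    # outpatient activity
    p_contact: float = 0.944
    contact_rate: float = 9.5
    p_dc_setting: float = 0.10  # share of generic contacts delivered in day centres
    p_psychiatric_visit: float = 0.81
    visit_rate: float = 4.0
    p_assessment: float = 0.038
    assessment_rate: float = 1.0
    p_psychosocial: float = 0.532
    psychosocial_rate: float = 4.5
    p_psychoeducation: float = 0.038
    psychoeducation_rate: float = 2.6
    p_psychotherapy: float = 0.192
    psychotherapy_rate: float = 5.7
    p_family: float = 0.25
    family_rate: float = 2.0
    p_community_persistent: float = 0.612

    # pharmacotherapy
    p_antipsychotic: float = 0.491
    p_lithium: float = 0.038
    p_vpa_cbz: float = 0.184
    p_lamotrigine: float = 0.05
    p_other_mood_stabilizer: float = 0.25
    p_antidepressant: float = 0.461
    p_drug_persistent: float = 0.54

    # hospital and residential care
    p_ghpw_admission: float = 0.127
    ghpw_los_median: float = 12.0
    ghpw_los_sdlog: float = 0.55
    p_unplanned_first: float = 0.9
    p_readmission_7d: float = 0.15
    p_readmission_30d: float = 0.285  # cumulative with the 7-day probability
    p_residential: float = 0.157
    residential_los_median: float = 70.0
    residential_los_sdlog: float = 1.0
    p_followup_14d: float = 0.60
    p_followup_psych: float = 0.60  # share of follow-up contacts that are psychiatric visits
    p_home_follow: float = 0.04

    # monitoring of pharmacotherapy
    p_monitor: dict = field(
        default_factory=lambda: {
            "antipsychotic": 0.256,
            "lithium": 0.618,
            "valproate_carbamazepine": 0.478,
            "lamotrigine": 0.415,
        }
    )
    p_partial_monitor: float = 0.30

    # washout contamination and mortality
    p_contaminated_older: float = 0.5  # disqualifier plant rate in over-40 patients
    baseline_mortality: dict = field(default_factory=lambda: dict(DEFAULT_MORTALITY))
    smr_true: float = 2.06

    # regionally unavailable information ("psychoeducation", "home", ...)
    unavailable_services: tuple = ()

    def validate(self) -> None:
        probs = {
            name: getattr(self, name)
            for name in vars(self)
            if name.startswith("p_") and isinstance(getattr(self, name), float)
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} = {v} outside [0, 1]")
        for cls, v in self.p_monitor.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"p_monitor[{cls}] = {v} outside [0, 1]")
        if self.n_adults <= 0:
            raise ConfigurationError("n_adults must be positive")
        if self.prevalence_per_10k < 0 or self.incidence_per_10k < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.p_readmission_30d < self.p_readmission_7d:
            raise ConfigurationError("p_readmission_30d is cumulative and must be >= p_readmission_7d")


@dataclass
class GenerationResult:
    """A generated region: the event store, its ground-truth ledger (one row
    per cohort patient), and the population strata used for rates."""

    store: EventStore
    ledger: pd.DataFrame
    strata: pd.DataFrame
    scenario: RegionScenario


# ---------------------------------------------------------------------------
# day-grid truth routines (independent of mhqi.episodes interval arithmetic)
# ---------------------------------------------------------------------------


def _mark(covered: np.ndarray, start: int, stop: int) -> None:
    """Mark [start, stop) on a window-relative boolean grid, clipped."""
    n = len(covered)
    covered[max(start, 0) : max(min(stop, n), 0)] = True


def _max_uncovered_run(covered: np.ndarray) -> int:
    u = (~covered).astype(np.int8)
    if not u.any():
        return 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], u, [0]))))
    runs = edges.reshape(-1, 2)
    return int((runs[:, 1] - runs[:, 0]).max())


def grid_community_persistent(
    contact_days: Sequence[int],
    window_days: int,
    bridge_intervals: Sequence[tuple[int, int]] = (),
    gap_days: int = 90,
) -> bool:
    """Day-grid truth: persistent iff no uncovered run of >= gap_days."""
    covered = np.zeros(window_days, dtype=bool)
    for d in contact_days:
        if 0 <= d < window_days:
            covered[d] = True
    for s, e in bridge_intervals:
        _mark(covered, s, e + 1)
    return _max_uncovered_run(covered) < gap_days


def grid_drug_persistent(
    dispensations: Sequence[tuple[int, float]],
    window_days: int,
    bridge_intervals: Sequence[tuple[int, int]] = (),
    gap_days: int = 90,
) -> Optional[bool]:
    """Day-grid truth for drug persistence.

    Marks supplied days (with stockpiling carry-forward) and bridge days on a
    grid, then checks that from the first in-window dispensation onward no
    two consecutive covered days — nor the stretch from the last covered day
    to the last observed day — are >= gap_days apart.  Returns ``None`` when
    the patient has no dispensation inside the window (not assessable).
    """
    disp = sorted((d, q) for d, q in dispensations if q > 0)
    anchors = [d for d, _ in disp if 0 <= d < window_days]
    if not anchors:
        return None
    lo = min(disp[0][0], 0)
    n = window_days - lo
    covered = np.zeros(n, dtype=bool)
    ptr = lo - 1  # last supplied absolute day
    for d, q in disp:
        dur = math.ceil(q)
        start = max(d, ptr + 1)
        _mark(covered, start - lo, start - lo + dur)
        ptr = max(ptr, start + dur - 1)
    for s, e in bridge_intervals:
        _mark(covered, s - lo, e + 1 - lo)
    days = np.flatnonzero(covered) + lo
    days = days[days >= anchors[0]]
    days = np.append(days[days < window_days], window_days - 1)
    return bool((np.diff(np.concatenate(([anchors[0]], days))) < gap_days).all())


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _region_rng(scenario: RegionScenario, seed: Optional[int]) -> np.random.Generator:
    base = scenario.seed if seed is None else seed
    return np.random.default_rng([base % (2**31), zlib.crc32(scenario.region.encode())])


def _birth_date(index: date, age: int, rng: np.random.Generator) -> date:
    """A birth date giving exactly ``age`` completed years at ``index``."""
    offset = int(rng.integers(0, 365))
    anchor = index - timedelta(days=offset)
    try:
        return anchor.replace(year=anchor.year - age)
    except ValueError:  # Feb 29 anchor
        return anchor.replace(year=anchor.year - age, day=28)


def _stratum_counts(
    scenario: RegionScenario, rng: np.random.Generator
) -> tuple[dict, dict]:
    """Prevalent and newly counts per (band, sex) stratum."""
    shares = scenario.population_shares
    pops = {k: int(round(scenario.n_adults * v)) for k, v in shares.items()}
    if scenario.n_prevalent is not None:
        keys = list(pops)
        probs = np.array([pops[k] for k in keys], dtype=float)
        counts = rng.multinomial(scenario.n_prevalent, probs / probs.sum())
        n_prev = dict(zip(keys, (int(c) for c in counts)))
    else:
        n_prev = {
            k: int(rng.binomial(p, scenario.prevalence_per_10k / 1e4))
            for k, p in pops.items()
        }
    young = [k for k in pops if k[0] == "18-40"]
    if scenario.n_newly is not None:
        probs = np.array([pops[k] for k in young], dtype=float)
        counts = rng.multinomial(scenario.n_newly, probs / probs.sum())
        n_new = dict(zip(young, (int(c) for c in counts)))
    else:
        n_new = {
            k: int(rng.binomial(pops[k], scenario.incidence_per_10k / 1e4))
            for k in young
        }
    for k in young:  # newly is a sub-cohort of prevalent
        n_new[k] = min(n_new[k], n_prev[k])
    return (
        {"pops": pops, "prev": n_prev},
        n_new,
    )


def _count(rng: np.random.Generator, rate: float, exposure: float) -> int:
    """At-least-one event count with mean ~ rate x exposure."""
    lam = max(rate * exposure - 1.0, 0.0)
    return 1 + int(rng.poisson(lam))


def _persistent_contact_days(rng: np.random.Generator, w1: int) -> list[int]:
    """Contact days guaranteeing every uncovered run < 90 days."""
    days, d = [], 0
    while d < w1:
        days.append(d)
        d += int(rng.integers(55, 85))
    return days


def generate_region(
    scenario: RegionScenario, seed: Optional[int] = None
) -> GenerationResult:
    """Generate one region's bundle plus its ground-truth ledger.

    ``seed`` overrides ``scenario.seed``; the stream is additionally keyed
    by the region label so multi-region runs are independent.
    """
    s = scenario
    s.validate()
    rng = _region_rng(s, seed)
    year_start = date(s.recruitment_year, 1, 1)
    horizon = (
        year_start - timedelta(days=730),
        date(s.recruitment_year + 1, 12, 31),
    )
    horizon_last = (horizon[1] - year_start).days

    counts, n_new = _stratum_counts(s, rng)

    patients, contacts, admissions, dispensations = [], [], [], []
    residential, labs, diagnoses = [], [], []
    ledger_rows = []
    pid_counter = 0

    def visit_prob(p: float) -> float:
        # conditional probability given >=1 contact, preserving the marginal
        return min(p / s.p_contact, 1.0) if s.p_contact > 0 else 0.0

    for (band, sex), n_prev_stratum in counts["prev"].items():
        n_newly_stratum = n_new.get((band, sex), 0)
        for i in range(n_prev_stratum):
            pid_counter += 1
            pid = f"{s.region}-{pid_counter:06d}"
            is_newly = i < n_newly_stratum

            if band == "18-40":
                age = int(rng.integers(18, 41))
            else:
                age = int(rng.integers(41, 66))
            index_off = int(rng.integers(0, 365))  # day within recruitment year
            index = year_start + timedelta(days=index_off)
            birth = _birth_date(index, age, rng)

            # mortality: baseline hazard scaled by the true SMR
            haz = s.baseline_mortality[(band, sex)] * s.smr_true
            died = rng.random() < 1.0 - math.exp(-haz)
            delta = int(rng.integers(1, 365)) if died else 365
            w1 = delta  # active follow-up days, window is [0, w1)
            death = index + timedelta(days=delta) if died else None

            def day(rel: int) -> date:
                return index + timedelta(days=rel)

            # independent draws keep every cohort-level marginal exact; a
            # patient without outpatient CMHC/DC contact still reaches the
            # services at the index date via ward, residential or home care
            has_contact = rng.random() < s.p_contact
            has_ghpw = rng.random() < s.p_ghpw_admission
            has_res = rng.random() < s.p_residential
            if has_contact:
                entry_via = "contact"
            elif has_ghpw:
                entry_via = "ghpw"
            elif has_res:
                entry_via = "res"
            else:
                entry_via = "home"

            # ---- outpatient contacts -----------------------------------
            contact_days: list[tuple[int, str, str]] = []  # (rel day, setting, type)
            if entry_via == "home":
                contact_days.append((0, "home", "other"))
            if has_contact:
                persistent_plan = rng.random() < s.p_community_persistent
                if persistent_plan:
                    anchor_days = _persistent_contact_days(rng, w1)
                    stop = w1  # events may fall anywhere in the window
                else:
                    # leave a contact-free tail of >= 90 days (hospital or
                    # residential days may still bridge it)
                    stop = max(1, min(w1 - 90, w1))
                    anchor_days = [0] + [
                        int(rng.integers(0, stop))
                        for _ in range(int(rng.integers(0, 3)))
                    ]
                for p, rate, itype in (
                    (s.p_psychiatric_visit, s.visit_rate, "psychiatric_visit"),
                    (s.p_assessment, s.assessment_rate, "standardized_assessment"),
                    (s.p_psychosocial, s.psychosocial_rate, "psychosocial_intervention"),
                    (s.p_psychoeducation, s.psychoeducation_rate, "psychoeducation"),
                    (s.p_psychotherapy, s.psychotherapy_rate, "psychotherapy"),
                    (s.p_family, s.family_rate, "family_intervention"),
                ):
                    if itype == "psychoeducation" and "psychoeducation" in s.unavailable_services:
                        continue
                    if rng.random() < visit_prob(p):
                        for d in rng.integers(0, stop, size=_count(rng, rate, w1 / 365.0)):
                            contact_days.append((int(d), "CMHC", itype))
                # generic contacts sized so the *total* stream matches contact_rate
                n_extra = max(
                    _count(rng, s.contact_rate, w1 / 365.0)
                    - len(contact_days)
                    - len(anchor_days),
                    0,
                )
                extra = rng.integers(0, stop, size=n_extra)
                for d in sorted(list(anchor_days) + [int(x) for x in extra]):
                    setting = "DC" if rng.random() < s.p_dc_setting else "CMHC"
                    contact_days.append((d, setting, "other"))

            # ---- residential stays -------------------------------------
            res_intervals: list[tuple[int, Optional[int]]] = []
            if has_res:
                entry_rel = 0 if entry_via == "res" else int(rng.integers(0, w1))
                los = max(1, int(round(rng.lognormal(math.log(s.residential_los_median), s.residential_los_sdlog))))
                exit_rel: Optional[int] = entry_rel + los
                if died and exit_rel >= delta:
                    exit_rel = delta
                elif exit_rel > horizon_last - index_off:
                    exit_rel = None  # still resident at the end of the data horizon
                res_intervals.append((entry_rel, exit_rel))

            # ---- GHPW admissions ---------------------------------------
            adm_intervals: list[tuple[int, int, str]] = []  # (adm, disch, planned_flag)
            if has_ghpw:
                a0 = 0 if entry_via == "ghpw" else int(rng.integers(0, w1))
                prev_disch = None
                a = a0
                first = True
                while True:
                    los = max(1, int(round(rng.lognormal(math.log(s.ghpw_los_median), s.ghpw_los_sdlog))))
                    disch = a + los
                    if died:
                        disch = min(disch, delta)
                    disch = min(disch, horizon_last - index_off)
                    planned = "unplanned"
                    if first and rng.random() >= s.p_unplanned_first:
                        planned = "planned"
                    adm_intervals.append((a, disch, planned))
                    first = False
                    # chained readmission
                    u = rng.random()
                    if u < s.p_readmission_7d:
                        gap = int(rng.integers(1, 8))
                    elif u < s.p_readmission_30d:
                        gap = int(rng.integers(8, 31))
                    elif u < s.p_readmission_30d + 0.10:
                        gap = int(rng.integers(31, 121))
                    else:
                        break
                    a = disch + gap
                    if a >= w1 or len(adm_intervals) >= 4:
                        break

            # ---- discharge follow-up contacts --------------------------
            for a, disch, _ in adm_intervals:
                if disch + 14 >= w1:
                    continue
                if has_contact and rng.random() < s.p_followup_14d:
                    d = disch + int(rng.integers(1, 15))
                    itype = (
                        "psychiatric_visit"
                        if rng.random() < s.p_followup_psych
                        else "other"
                    )
                    contact_days.append((d, "CMHC", itype))
                if "home" not in s.unavailable_services and rng.random() < s.p_home_follow:
                    contact_days.append((disch + int(rng.integers(1, 15)), "home", "other"))

            # ---- drug dispensations ------------------------------------
            class_flags = {
                "antipsychotic": rng.random() < s.p_antipsychotic,
                "lithium": rng.random() < s.p_lithium,
                "valproate_carbamazepine": rng.random() < s.p_vpa_cbz,
                "lamotrigine": rng.random() < s.p_lamotrigine,
                "other_mood_stabilizer": rng.random() < s.p_other_mood_stabilizer,
                "antidepressant": rng.random() < s.p_antidepressant,
            }
            disp_rows: list[tuple[int, str, float]] = []  # (rel day, atc, ddd)
            for cls, treated in class_flags.items():
                if not treated:
                    continue
                f = int(rng.integers(0, min(60, w1)))
                codes = _ATC_BY_CLASS[cls]
                if rng.random() < s.p_drug_persistent:
                    d = f
                    while d < w1:
                        disp_rows.append((d, codes[int(rng.integers(len(codes)))], float(rng.integers(28, 31))))
                        d += int(rng.integers(25, 33))
                else:
                    n_fills = int(rng.integers(1, 3))
                    d = f
                    for _ in range(n_fills):
                        if d >= w1:
                            break
                        disp_rows.append((d, codes[int(rng.integers(len(codes)))], float(rng.integers(28, 31))))
                        d += int(rng.integers(20, 51))

            # ---- monitoring labs ---------------------------------------
            lab_codes: list[str] = []
            for cls, panel in _MONITOR_PANELS.items():
                if not class_flags[cls]:
                    continue
                if rng.random() < s.p_monitor[cls]:
                    lab_codes.extend(panel)
                elif rng.random() < s.p_partial_monitor and len(panel) > 1:
                    lab_codes.append(panel[int(rng.integers(len(panel)))])
            for code in lab_codes:
                labs.append((pid, day(int(rng.integers(0, w1))), code))
            # realized truth: panels can be cross-completed by another class
            emitted = set(lab_codes)
            monitored: dict[str, Optional[bool]] = {
                cls: (set(panel) <= emitted if class_flags[cls] else None)
                for cls, panel in _MONITOR_PANELS.items()
            }

            # ---- washout contamination (non-newly patients) -------------
            reasons: set[str] = set()
            if not is_newly:
                if age > 40:
                    reasons.add("age_out_of_range")
                    plant = rng.random() < s.p_contaminated_older
                else:
                    plant = True  # young non-newly must carry a disqualifier
                if plant:
                    choices = rng.random(3)
                    picks = [EXCLUSION_REASONS[j] for j in range(3) if choices[j] < 0.5]
                    if not picks:
                        picks = [EXCLUSION_REASONS[int(rng.integers(3))]]
                    for r in picks:
                        reasons.add(r)
                        if r == "prior_diagnosis":
                            dd = index - timedelta(days=int(rng.integers(30, 701)))
                            code = _PD_CODES[s.icd_dialect][int(rng.integers(4))]
                            diagnoses.append((pid, dd, code, "MHIS"))
                        elif r == "prior_ghpw_admission":
                            off = int(rng.integers(40, 651))
                            a_d = year_start - timedelta(days=off)
                            admissions.append(
                                (pid, "GHPW", a_d, a_d + timedelta(days=int(rng.integers(2, 21))), "unplanned", None)
                            )
                        elif r == "prior_psychotropic_use":
                            d1 = int(rng.integers(150, 651))
                            d2 = d1 - int(rng.integers(35, 81))
                            atc = _ATC_BY_CLASS["antidepressant"][0]
                            dispensations.append((pid, index - timedelta(days=d1), atc, 30.0))
                            dispensations.append((pid, index - timedelta(days=d2), atc, 30.0))

            # ---- qualifying diagnosis and registry ----------------------
            diagnoses.append(
                (pid, index, _PD_CODES[s.icd_dialect][int(rng.integers(4))], "MHIS")
            )
            patients.append((pid, birth, sex, death))

            # ---- materialize events -------------------------------------
            for d, setting, itype in contact_days:
                contacts.append((pid, day(d), setting, itype, None))
            for a, disch, planned in adm_intervals:
                admissions.append((pid, "GHPW", day(a), day(disch), planned, None))
            for entry_rel, exit_rel in res_intervals:
                residential.append(
                    (pid, day(entry_rel), day(exit_rel) if exit_rel is not None else None)
                )
            for d, atc, q in disp_rows:
                dispensations.append((pid, day(d), atc, q))

            # ---- post-hoc ledger truth ----------------------------------
            bridge = [(a, disch - 1) for a, disch, _ in adm_intervals if disch > a]
            bridge += [
                (e0, (e1 if e1 is not None else w1) - 1)
                for e0, e1 in res_intervals
                if (e1 if e1 is not None else w1) > e0
            ]
            cmhc_dc_days = [d for d, st, _ in contact_days if st in ("CMHC", "DC")]
            comm_pers = grid_community_persistent(cmhc_dc_days, w1, bridge)
            ms_disp = [
                (d, q)
                for d, atc, q in disp_rows
                if atc.startswith("N03A") or atc == "N05AN01"
            ]
            ms_pers = grid_drug_persistent(ms_disp, w1, bridge)

            res_days = sum(
                max(min((e1 if e1 is not None else w1), w1) - max(e0, 0), 0)
                for e0, e1 in res_intervals
            )
            ghpw_days = sum(disch - a for a, disch, _ in adm_intervals)
            n_long = sum(1 for a, disch, _ in adm_intervals if disch - a > 30)
            n_re7 = n_re30 = 0
            for k in range(1, len(adm_intervals)):
                gap = adm_intervals[k][0] - adm_intervals[k - 1][1]
                if adm_intervals[k][2] == "unplanned":
                    if gap <= 7:
                        n_re7 += 1
                    if gap <= 30:
                        n_re30 += 1
            n_disch_obs = n_fa = n_fp = n_fh = 0
            cd_sorted = sorted(contact_days)
            for a, disch, _ in adm_intervals:
                if disch + 14 >= w1:
                    continue
                n_disch_obs += 1
                win = [c for c in cd_sorted if disch < c[0] <= disch + 14]
                if any(True for c in win):
                    n_fa += 1
                if any(c[2] == "psychiatric_visit" for c in win):
                    n_fp += 1
                if any(c[1] == "home" for c in win):
                    n_fh += 1

            counts_by_type = {}
            for t in (
                "psychiatric_visit",
                "standardized_assessment",
                "psychosocial_intervention",
                "psychoeducation",
                "psychotherapy",
                "family_intervention",
            ):
                counts_by_type[t] = sum(1 for c in contact_days if c[2] == t)

            ms_treated = any(
                class_flags[c]
                for c in ("lithium", "valproate_carbamazepine", "lamotrigine", "other_mood_stabilizer")
            )
            ledger_rows.append(
                {
                    "patient_id": pid,
                    "region": s.region,
                    "sex": sex,
                    "age_band": band,
                    "age_at_index": age,
                    "is_newly": is_newly,
                    "exclusion_reasons": ";".join(sorted(reasons)),
                    "index_date": index,
                    "death_date": death,
                    "died": died,
                    "person_years": 1.0 if not died else delta / 365.25,
                    "n_contacts_cmhc_dc": len(cmhc_dc_days),
                    "n_contacts_cmhc": sum(1 for _, st, _ in contact_days if st == "CMHC"),
                    "n_psychiatric_visits": counts_by_type["psychiatric_visit"],
                    "n_assessments": counts_by_type["standardized_assessment"],
                    "n_psychosocial": counts_by_type["psychosocial_intervention"],
                    "n_psychoeducation": counts_by_type["psychoeducation"],
                    "n_psychotherapy": counts_by_type["psychotherapy"],
                    "n_family": counts_by_type["family_intervention"],
                    "treated_antipsychotic": class_flags["antipsychotic"],
                    "treated_lithium": class_flags["lithium"],
                    "treated_vpa_cbz": class_flags["valproate_carbamazepine"],
                    "treated_lamotrigine": class_flags["lamotrigine"],
                    "treated_mood_stabilizer": ms_treated,
                    "treated_antidepressant": class_flags["antidepressant"],
                    "has_residential": len(res_intervals) > 0,
                    "residential_days": res_days,
                    "has_ghpw": len(adm_intervals) > 0,
                    "ghpw_days": ghpw_days,
                    "n_admissions": len(adm_intervals),
                    "n_long_admissions": n_long,
                    "n_readmissions_7d": n_re7,
                    "n_readmissions_30d": n_re30,
                    "n_discharges_observable": n_disch_obs,
                    "n_discharges_followed_any": n_fa,
                    "n_discharges_followed_psych": n_fp,
                    "n_discharges_followed_home": n_fh,
                    "community_persistent": comm_pers,
                    "ms_persistent": ms_pers,
                    "monitored_antipsychotic": monitored["antipsychotic"],
                    "monitored_lithium": monitored["lithium"],
                    "monitored_vpa_cbz": monitored["valproate_carbamazepine"],
                    "monitored_lamotrigine": monitored["lamotrigine"],
                }
            )

    # background patients: registered, seen, but never diagnosed in-cohort
    for i in range(s.n_background):
        pid_counter += 1
        pid = f"{s.region}-{pid_counter:06d}"
        d0 = year_start + timedelta(days=int(rng.integers(0, 365)))
        age = int(rng.integers(18, 66))
        patients.append((pid, _birth_date(d0, age, rng), "F" if rng.random() < 0.5 else "M", None))
        for _ in range(int(rng.integers(1, 4))):
            contacts.append(
                (pid, d0 + timedelta(days=int(rng.integers(0, 200))), "CMHC", "other", None)
            )

    store = EventStore(
        region=s.region,
        horizon=horizon,
        icd_dialect=s.icd_dialect,
        unavailable_services=tuple(s.unavailable_services),
    )
    store.patients = pd.DataFrame(
        patients, columns=["patient_id", "birth_date", "sex", "death_date"]
    )
    store.contacts = pd.DataFrame(
        contacts, columns=["patient_id", "date", "setting", "intervention_type", "provider_role"]
    )
    store.admissions = pd.DataFrame(
        admissions,
        columns=["patient_id", "ward_type", "admission_date", "discharge_date", "planned_flag", "diagnosis_codes"],
    )
    store.dispensations = pd.DataFrame(
        dispensations, columns=["patient_id", "date", "atc_code", "n_ddd"]
    )
    store.residential = pd.DataFrame(
        residential, columns=["patient_id", "entry_date", "exit_date"]
    )
    store.lab_services = pd.DataFrame(labs, columns=["patient_id", "date", "service_code"])
    store.diagnoses = pd.DataFrame(
        diagnoses, columns=["patient_id", "date", "icd_code", "source"]
    )
    for name, df in store.tables():
        for col in {
            "patients": ("birth_date", "death_date"),
            "contacts": ("date",),
            "admissions": ("admission_date", "discharge_date"),
            "dispensations": ("date",),
            "residential": ("entry_date", "exit_date"),
            "lab_services": ("date",),
            "diagnoses": ("date",),
        }[name]:
            df[col] = pd.to_datetime(df[col])

    ledger = pd.DataFrame(ledger_rows)
    strata = pd.DataFrame(
        [
            {
                "region": s.region,
                "age_band": band,
                "sex": sex,
                "population": counts["pops"][(band, sex)],
                "n_prevalent": counts["prev"][(band, sex)],
                "n_newly": n_new.get((band, sex), 0),
            }
            for (band, sex) in counts["pops"]
        ]
    )
    return GenerationResult(store=store, ledger=ledger, strata=strata, scenario=s)


def generate_multiregion(
    scenarios: Sequence[RegionScenario], seed: Optional[int] = None
) -> list[GenerationResult]:
    """Generate several regions with independent, label-keyed streams."""
    labels = [sc.region for sc in scenarios]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate region labels: {labels}")
    return [generate_region(sc, seed=seed) for sc in scenarios]


# ---------------------------------------------------------------------------
# study-shaped default scenarios
# ---------------------------------------------------------------------------


def default_scenarios(scale: float = 1.0, seed: int = 0) -> list[RegionScenario]:
    """Four regional scenarios shaped like a large multi-regional survey of
    personality-disorder care: three large regions and one small province,
    with heterogeneous access, treatment and admission parameters.

    ``scale`` shrinks cohort sizes proportionally for quick runs.
    """
    specs = [
        # region, n_prev, n_newly, prev/10k, inc/10k, p_contact, rate, p_visit,
        # p_psycho, p_pther, p_ap, p_vpa, p_res, p_ghpw, p_comm, dialect
        ("north-a", 16196, 883, 19.5, 3.4, 0.923, 8.0, 0.817, 0.524, 0.207, 0.487, 0.168, 0.175, 0.142, 0.688, "icd10", ()),
        ("north-b", 9462, 609, 25.3, 5.5, 0.984, 13.0, 0.839, 0.515, 0.095, 0.566, 0.180, 0.168, 0.124, 0.584, "icd9cm", ("home",)),
        ("island", 934, 106, 9.0, 2.8, 0.742, 7.0, 0.651, 0.526, 0.197, 0.328, 0.263, 0.020, 0.122, 0.332, "icd10", ()),
        ("centre", 5096, 733, 10.4, 4.7, 0.974, 10.0, 0.765, 0.590, 0.324, 0.392, 0.228, 0.102, 0.086, 0.471, "icd10", ("psychoeducation",)),
    ]
    out = []
    for (
        region, n_prev, n_newly, prev, inc, p_c, rate, p_v, p_ps, p_pt,
        p_ap, p_vpa, p_res, p_g, p_comm, dialect, unavailable,
    ) in specs:
        n_prev_s = max(1, int(round(n_prev * scale)))
        n_newly_s = max(1, int(round(n_newly * scale)))
        out.append(
            RegionScenario(
                region=region,
                seed=seed,
                icd_dialect=dialect,
                n_adults=int(round(n_prev_s / prev * 1e4)),
                prevalence_per_10k=prev,
                incidence_per_10k=inc,
                n_prevalent=n_prev_s,
                n_newly=n_newly_s,
                p_contact=p_c,
                contact_rate=rate,
                p_psychiatric_visit=p_v,
                p_psychosocial=p_ps,
                p_psychotherapy=p_pt,
                p_antipsychotic=p_ap,
                p_vpa_cbz=p_vpa,
                p_residential=p_res,
                p_ghpw_admission=p_g,
                p_community_persistent=p_comm,
                unavailable_services=unavailable,
            )
        )
    return out
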