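"""Indicator catalogue: worked examples, oracles and ledger equality."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from mhqi.indicators import INDICATOR_IDS, compute_indicators, median_per_py

from conftest import make_store


def members_frame(pids, index=date(2015, 3, 1), deaths=None):
    deaths = deaths or {}
    return pd.DataFrame(
        {
            "patient_id": list(pids),
            "cohort": "prevalent",
            "index_date": index,
            "follow_up_end": index + timedelta(days=365),
            "age_at_index": 30,
            "sex": "F",
            "death_date": [deaths.get(p) for p in pids],
            "person_years": [
                1.0 if p not in deaths else (deaths[p] - index).days / 365.25
                for p in pids
            ],
        }
    )


def test_admission_proportion_arithmetic():
    """4 admitted patients out of a cohort of 10 give 40.0%."""
    pids = [f"p{i}" for i in range(10)]
    store = make_store(
        patients=[(p, date(1985, 1, 1), "F", None) for p in pids],
        admissions=[
            (p, "GHPW", date(2015, 6, 1), date(2015, 6, 8), "unplanned")
            for p in pids[:4]
        ],
    )
    results, _ = compute_indicators(store, members_frame(pids), "prevalent", only={"19"})
    row = results.iloc[0]
    assert (row["numerator"], row["denominator"], row["value"]) == (4, 10, 40.0)


def test_psychotherapy_sessions_enter_the_median_pool():
    """Six psychotherapy sessions over one person-year contribute a rate of
    6.0 to the intensity median."""
    store = make_store(
        patients=[("p0", date(1985, 1, 1), "F", None)],
        contacts=[
            ("p0", date(2015, 3, 1) + timedelta(days=30 * k), "CMHC", "psychotherapy")
            for k in range(6)
        ],
    )
    _, samples = compute_indicators(store, members_frame(["p0"]), "prevalent", only={"12"})
    assert samples["12"].tolist() == [6.0]


@pytest.mark.parametrize(
    "rates,expected", [([2, 4, 9], 4.0), ([2, 4], 3.0), ([5], 5.0)]
)
def test_median_per_py_examples(rates, expected):
    assert median_per_py(np.array(rates, dtype=float)) == expected


def test_median_per_py_matches_sort_and_pick():
    rng = np.random.default_rng(0)
    for _ in range(200):
        x = rng.uniform(0, 50, size=rng.integers(1, 40))
        s = np.sort(x)
        n = len(s)
        want = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert median_per_py(x) == pytest.approx(want)


def test_readmission_windows():
    """Discharge day 10, unplanned readmission day 15: counts for both the
    7- and 30-day indicators; a readmission on day 45 counts for neither."""
    idx = date(2015, 3, 1)

    def run(gap_days):
        store = make_store(
            patients=[("p0", date(1985, 1, 1), "F", None)],
            admissions=[
                ("p0", "GHPW", idx + timedelta(days=5), idx + timedelta(days=10), "unplanned"),
                (
                    "p0",
                    "GHPW",
                    idx + timedelta(days=10 + gap_days),
                    idx + timedelta(days=16 + gap_days),
                    "unplanned",
                ),
            ],
        )
        res, _ = compute_indicators(store, members_frame(["p0"]), "prevalent", only={"22", "23"})
        return res.set_index("indicator_id")["numerator"].to_dict()

    assert run(5) == {"22": 1, "23": 1}
    assert run(35) == {"22": 0, "23": 0}
    assert run(20) == {"22": 0, "23": 1}


def test_planned_readmission_does_not_count():
    idx = date(2015, 3, 1)
    store = make_store(
        patients=[("p0", date(1985, 1, 1), "F", None)],
        admissions=[
            ("p0", "GHPW", idx, idx + timedelta(days=5), "unplanned"),
            ("p0", "GHPW", idx + timedelta(days=8), idx + timedelta(days=12), "planned"),
        ],
    )
    res, _ = compute_indicators(store, members_frame(["p0"]), "prevalent", only={"22", "23"})
    assert res["numerator"].sum() == 0
    assert res.set_index("indicator_id").at["22", "denominator"] == 2


def test_readmissions_match_pairwise_scan_oracle():
    """Fuzzed admission histories: the indicator counts equal a brute-force
    scan over all (previous discharge, admission) pairs."""
    rng = np.random.default_rng(31)
    idx = date(2015, 3, 1)
    for _ in range(120):
        n = int(rng.integers(1, 6))
        rows, cursor = [], 0
        for _ in range(n):
            cursor += int(rng.integers(1, 60))
            start = cursor
            cursor += int(rng.integers(1, 40))
            if cursor >= 360:
                break
            rows.append(
                (start, cursor, "unplanned" if rng.random() < 0.7 else "planned")
            )
        if not rows:
            continue
        store = make_store(
            patients=[("p0", date(1985, 1, 1), "F", None)],
            admissions=[
                ("p0", "GHPW", idx + timedelta(days=a), idx + timedelta(days=d), fl)
                for a, d, fl in rows
            ],
        )
        res, _ = compute_indicators(
            store, members_frame(["p0"]), "prevalent", only={"22", "23"}
        )
        got = res.set_index("indicator_id")["numerator"].to_dict()
        want7 = want30 = 0
        for k, (a, d, fl) in enumerate(rows):
            if k == 0 or fl != "unplanned":
                continue
            prev_discharge = rows[k - 1][1]
            if a - prev_discharge <= 7:
                want7 += 1
            if a - prev_discharge <= 30:
                want30 += 1
        assert got == {"22": want7, "23": want30}


def test_monitoring_panels_require_complete_sets():
    idx = date(2015, 3, 1)
    store = make_store(
        patients=[("p0", date(1985, 1, 1), "F", None), ("p1", date(1985, 1, 1), "F", None)],
        dispensations=[
            ("p0", idx, "N05AH04", 30),
            ("p1", idx, "N05AH04", 30),
        ],
        lab_services=[
            ("p0", idx + timedelta(days=30), "glycaemia"),
            ("p0", idx + timedelta(days=60), "lipid_panel"),
            ("p1", idx + timedelta(days=30), "glycaemia"),  # panel incomplete
        ],
    )
    res, _ = compute_indicators(store, members_frame(["p0", "p1"]), "prevalent", only={"29"})
    row = res.iloc[0]
    assert (row["numerator"], row["denominator"]) == (1, 2)


def test_unavailable_service_flags_indicator(small_multiregion):
    by_region = {r.scenario.region: r for r in small_multiregion}
    gamma = by_region["gamma"]  # psychoeducation not recorded
    res, _ = compute_indicators(gamma.store, _members_from_ledger(gamma.ledger), "prevalent")
    res = res.set_index("indicator_id")
    assert not res.at["9", "n_available"]
    assert not res.at["10", "n_available"]
    assert res.at["11", "n_available"]
    beta = by_region["beta"]  # home care not recorded
    res_b, _ = compute_indicators(beta.store, _members_from_ledger(beta.ledger), "prevalent")
    assert not res_b.set_index("indicator_id").at["28", "n_available"]


def _members_from_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": ledger["patient_id"],
            "cohort": "prevalent",
            "index_date": ledger["index_date"],
            "follow_up_end": [d + timedelta(days=365) for d in ledger["index_date"]],
            "age_at_index": ledger["age_at_index"],
            "sex": ledger["sex"],
            "death_date": ledger["death_date"],
            "person_years": ledger["person_years"],
        }
    )


LEDGER_REDUCTIONS = {
    "1": lambda led: ((led["n_contacts_cmhc_dc"] > 0).sum(), len(led)),
    "3": lambda led: ((led["n_psychiatric_visits"] > 0).sum(), len(led)),
    "5": lambda led: ((led["n_assessments"] > 0).sum(), len(led)),
    "7": lambda led: ((led["n_psychosocial"] > 0).sum(), len(led)),
    "9": lambda led: ((led["n_psychoeducation"] > 0).sum(), len(led)),
    "11": lambda led: ((led["n_psychotherapy"] > 0).sum(), len(led)),
    "14": lambda led: (led["treated_antipsychotic"].sum(), len(led)),
    "15": lambda led: (led["treated_mood_stabilizer"].sum(), len(led)),
    "15a": lambda led: (led["treated_lithium"].sum(), len(led)),
    "15b": lambda led: (led["treated_vpa_cbz"].sum(), len(led)),
    "16": lambda led: (led["treated_antidepressant"].sum(), len(led)),
    "17": lambda led: (led["has_residential"].sum(), len(led)),
    "19": lambda led: (led["has_ghpw"].sum(), len(led)),
    "21": lambda led: (led["n_long_admissions"].sum(), led["n_admissions"].sum()),
    "22": lambda led: (led["n_readmissions_7d"].sum(), led["n_admissions"].sum()),
    "23": lambda led: (led["n_readmissions_30d"].sum(), led["n_admissions"].sum()),
    "24": lambda led: (led["community_persistent"].sum(), len(led)),
    "25": lambda led: (
        led[led["treated_mood_stabilizer"]]["ms_persistent"].map(bool).sum(),
        led["treated_mood_stabilizer"].sum(),
    ),
    "26": lambda led: (
        led["n_discharges_followed_any"].sum(),
        led["n_discharges_observable"].sum(),
    ),
    "27": lambda led: (
        led["n_discharges_followed_psych"].sum(),
        led["n_discharges_observable"].sum(),
    ),
    "28": lambda led: (
        led["n_discharges_followed_home"].sum(),
        led["n_discharges_observable"].sum(),
    ),
    "29": lambda led: (
        led[led["treated_antipsychotic"]]["monitored_antipsychotic"].map(bool).sum(),
        led["treated_antipsychotic"].sum(),
    ),
    "30": lambda led: (
        led[led["treated_lithium"]]["monitored_lithium"].map(bool).sum(),
        led["treated_lithium"].sum(),
    ),
    "31": lambda led: (
        led[led["treated_vpa_cbz"]]["monitored_vpa_cbz"].map(bool).sum(),
        led["treated_vpa_cbz"].sum(),
    ),
    "32": lambda led: (
        led[led["treated_lamotrigine"]]["monitored_lamotrigine"].map(bool).sum(),
        led["treated_lamotrigine"].sum(),
    ),
}

LEDGER_MEDIANS = {
    "2": "n_contacts_cmhc",
    "4": "n_psychiatric_visits",
    "6": "n_assessments",
    "8": "n_psychosocial",
    "10": "n_psychoeducation",
    "12": "n_psychotherapy",
    "13": "n_family",
    "18": "residential_days",
    "20": "ghpw_days",
}


def test_all_indicators_equal_ground_truth_ledger(small_region):
    """Every non-SMR indicator computed by the pipeline equals the value
    derived from the generator's ground-truth ledger."""
    store, ledger = small_region.store, small_region.ledger
    members = _members_from_ledger(ledger)
    results, samples = compute_indicators(store, members, "prevalent")
    results = results.set_index("indicator_id")
    for ind_id, reduce in LEDGER_REDUCTIONS.items():
        want_num, want_den = reduce(ledger)
        row = results.loc[ind_id]
        assert (row["numerator"], row["denominator"]) == (want_num, want_den), ind_id
    for ind_id, col in LEDGER_MEDIANS.items():
        users = ledger[ledger[col] > 0]
        want = float(np.median(users[col] / users["person_years"]))
        assert results.at[ind_id, "value"] == pytest.approx(want), ind_id
    # SMR observed deaths equal the ledger's
    assert results.at["33", "numerator"] == ledger["died"].sum()


def test_structural_nesting_invariants(small_region):
    store, ledger = small_region.store, small_region.ledger
    members = _members_from_ledger(ledger)
    results, _ = compute_indicators(store, members, "prevalent")
    r = results.set_index("indicator_id")
    assert r.at["22", "numerator"] <= r.at["23", "numerator"]
    assert r.at["27", "numerator"] <= r.at["26", "numerator"]
    assert r.at["25", "denominator"] == r.at["15", "numerator"]
    assert r.at["30", "denominator"] == r.at["15a", "numerator"]
    assert r.at["29", "denominator"] == r.at["14", "numerator"]
    # values reconstruct from counts exactly
    props = results[(results["kind"] == "proportion") & results["n_available"]]
    recon = 100.0 * props["numerator"] / props["denominator"]
    assert np.allclose(props["value"], recon, equal_nan=True)


def test_catalogue_covers_all_33_indicators():
    ids = set(INDICATOR_IDS)
    assert {str(i) for i in range(1, 34)} <= ids
    assert {"15a", "15b"} <= ids
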