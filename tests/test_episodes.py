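"""Episode construction and persistence against day-grid brute force.

The oracle simulates drug supply one day at a time (a stock counter that a
dispensation refills and each day depletes), marks hospital/residential days
covered, and applies the gap rule on the resulting day grid — entirely
independent of the interval arithmetic in the implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhqi.episodes import (
    build_episodes,
    community_persistence,
    drug_persistence,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_supply_days(disps, carryover=True):
    """Day-by-day stock simulation -> sorted list of supplied days."""
    disps = sorted((d, q) for d, q in disps if q > 0)
    if not disps:
        return []
    refills = {}
    for d, q in disps:
        refills[d] = refills.get(d, 0) + math.ceil(q)
    first = disps[0][0]
    total = sum(math.ceil(q) for _, q in disps)
    horizon = max(refills) + total + 2
    covered = []
    if carryover:
        stock = 0
        day = first
        while day < horizon:
            stock += refills.get(day, 0)
            if stock > 0:
                covered.append(day)
                stock -= 1
            day += 1
    else:
        marked = set()
        for d, q in disps:
            marked.update(range(d, d + math.ceil(q)))
        covered = sorted(marked)
    return covered


def oracle_episodes(disps, gap_days=90, carryover=True):
    """Blocks of covered days chained while end-to-start < gap_days."""
    covered = oracle_supply_days(disps, carryover)
    if not covered:
        return []
    blocks = []
    start = prev = covered[0]
    for d in covered[1:]:
        if d == prev + 1:
            prev = d
        else:
            blocks.append((start, prev))
            start = prev = d
    blocks.append((start, prev))
    episodes = []
    cur = [blocks[0]]
    for b in blocks[1:]:
        if b[0] - cur[-1][1] >= gap_days:
            episodes.append(cur)
            cur = [b]
        else:
            cur.append(b)
    episodes.append(cur)
    out = []
    for ep_blocks in episodes:
        s, e = ep_blocks[0][0], ep_blocks[-1][1]
        out.append((s, e, sum(b1 - b0 + 1 for b0, b1 in ep_blocks)))
    return out


def oracle_drug_persistent(disps, window, bridges=(), gap_days=90):
    """Covered-day scan: from the first in-window dispensation, consecutive
    covered days must never be >= gap_days apart, nor may the stretch from
    the last covered day to the last observed day reach gap_days."""
    w0, w1 = window
    anchors = [d for d, q in sorted(disps) if q > 0 and w0 <= d < w1]
    if not anchors:
        return None
    covered = set(oracle_supply_days(disps))
    for s, e in bridges:
        covered.update(range(s, e + 1))
    days = sorted(d for d in covered if anchors[0] <= d < w1) + [w1 - 1]
    prev = anchors[0]
    for d in days:
        if d - prev >= gap_days:
            return False
        prev = d
    return True


def oracle_community_persistent(contact_days, window, bridges=(), gap_days=90):
    w0, w1 = window
    covered = set(d for d in contact_days if w0 <= d < w1)
    for s, e in bridges:
        covered.update(range(max(s, w0), min(e, w1 - 1) + 1))
    run = 0
    for day in range(w0, w1):
        if day in covered:
            run = 0
        else:
            run += 1
            if run >= gap_days:
                return False
    return True


def random_instance(rng):
    n = int(rng.integers(1, 9))
    days = np.cumsum(rng.integers(0, 140, size=n))
    ddd = rng.integers(1, 95, size=n).astype(float)
    if rng.random() < 0.2:
        ddd[rng.integers(n)] += rng.random()  # fractional DDD
    return list(zip((int(d) for d in days), (float(q) for q in ddd)))


# ---------------------------------------------------------------------------
# episode construction
# ---------------------------------------------------------------------------


def test_single_dispensation_defines_an_episode():
    (ep,) = build_episodes([(0, 30)])
    assert (ep.start_day, ep.end_day, ep.covered_days, ep.n_dispensations) == (0, 29, 30, 1)


def test_gap_rule_boundary_is_strict():
    """Supply ends day 29; a refill on day 119 sits exactly 90 days later,
    which already interrupts the episode — 89 days would not."""
    two = build_episodes([(0, 30), (119, 30)])
    assert len(two) == 2
    one = build_episodes([(0, 30), (118, 30)])
    assert len(one) == 1
    assert one[0].end_day == 147
    assert one[0].covered_days == 60  # the hole between supplies is not covered


def test_stockpiling_shifts_overlapping_supply_forward():
    (ep,) = build_episodes([(0, 30), (10, 30)])
    assert ep.end_day == 59
    assert ep.covered_days == 60
    (ep_nc,) = build_episodes([(0, 30), (10, 30)], carryover=False)
    assert ep_nc.end_day == 39
    assert ep_nc.covered_days == 40


def test_non_positive_quantities_are_dropped():
    assert build_episodes([(0, 0.0), (5, -3)]) == []


def test_order_invariance():
    disp = [(100, 10), (0, 30), (50, 20)]
    assert build_episodes(disp) == build_episodes(sorted(disp)) == build_episodes(disp[::-1])


@pytest.mark.parametrize("carryover", [True, False])
def test_episodes_match_day_grid_oracle(carryover):
    rng = np.random.default_rng(2024)
    for _ in range(300):
        disp = random_instance(rng)
        got = [
            (ep.start_day, ep.end_day, ep.covered_days)
            for ep in build_episodes(disp, carryover=carryover)
        ]
        assert got == oracle_episodes(disp, carryover=carryover)


@given(
    st.lists(
        st.tuples(st.integers(0, 400), st.integers(1, 120)), min_size=1, max_size=6
    )
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_episodes_match_oracle_hypothesis(pairs):
    disp = [(d, float(q)) for d, q in pairs]
    got = [(e.start_day, e.end_day, e.covered_days) for e in build_episodes(disp)]
    assert got == oracle_episodes(disp)


# ---------------------------------------------------------------------------
# drug persistence
# ---------------------------------------------------------------------------


def test_monthly_refills_all_year_are_persistent():
    disp = [(d, 30) for d in range(0, 365, 30)]
    verdict = drug_persistence(disp, (0, 365))
    assert verdict.persistent


def test_single_fill_at_index_is_discontinued_at_supply_end():
    verdict = drug_persistence([(0, 30)], (0, 365))
    assert not verdict.persistent
    assert verdict.first_gap_start == 30


def test_no_in_window_dispensation_means_not_assessable():
    assert drug_persistence([(-100, 30)], (0, 365)) is None


def test_hospital_stay_bridges_a_supply_gap():
    """A 100-day refill gap of which 40 days are spent in hospital is
    continuity of care: the hospital block splits the gap into sub-threshold
    pieces."""
    disp = [(0, 30), (130, 30), (160, 30), (190, 30), (220, 30), (250, 30), (280, 30)]
    bare = drug_persistence(disp, (0, 365))
    bridged = drug_persistence(disp, (0, 365), bridging_intervals=[(60, 99)])
    assert bridged.persistent
    assert bridged.persistent == oracle_drug_persistent(disp, (0, 365), [(60, 99)])
    assert bare.persistent == oracle_drug_persistent(disp, (0, 365))


def test_drug_persistence_matches_oracle_on_random_histories():
    rng = np.random.default_rng(99)
    for _ in range(300)  :
        disp = [(d - 200, q) for d, q in random_instance(rng)]
        bridges = []
        for _ in range(int(rng.integers(0, 3))):
            s = int(rng.integers(0, 330))
            bridges.append((s, s + int(rng.integers(1, 60))))
        got = drug_persistence(disp, (0, 365), bridges)
        want = oracle_drug_persistent(disp, (0, 365), bridges)
        assert (got is None) == (want is None)
        if got is not None:
            assert got.persistent == want


def test_adding_a_dispensation_never_hurts():
    """More supply can only extend coverage and never flips a persistent
    verdict to discontinued."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        disp = random_instance(rng)
        extra = (int(rng.integers(0, 500)), float(rng.integers(1, 60)))
        before = build_episodes(disp)
        after = build_episodes(disp + [extra])
        assert sum(e.covered_days for e in after) >= sum(e.covered_days for e in before)
        v0 = drug_persistence(disp, (0, 365))
        v1 = drug_persistence(disp + [extra], (0, 365))
        if v0 is not None and v0.persistent:
            assert v1.persistent


def test_gap_threshold_limits():
    disp = [(0, 10), (200, 10)]
    assert len(build_episodes(disp, gap_days=10**6)) == 1
    assert drug_persistence(disp, (0, 300), gap_days=10**6).persistent
    # gap of one day: only seamless daily coverage persists
    assert len(build_episodes(disp, gap_days=1)) == 2
    assert drug_persistence([(0, 300)], (0, 300), gap_days=1).persistent
    assert not drug_persistence([(0, 299)], (0, 300), gap_days=1).persistent


# ---------------------------------------------------------------------------
# community persistence
# ---------------------------------------------------------------------------


def test_monthly_contacts_are_persistent():
    assert community_persistence(range(0, 365, 30), (0, 365)).persistent


def test_single_contact_at_index_is_not_persistent():
    verdict = community_persistence([0], (0, 365))
    assert not verdict.persistent
    assert verdict.first_gap_start == 1


def test_uncovered_run_boundary():
    # contacts 90 days apart leave an 89-day uncovered run: still persistent
    assert community_persistence(range(0, 365, 90), (0, 365)).persistent
    assert not community_persistence([0, 91, 180, 270, 360], (0, 365)).persistent


def test_residential_stay_bridges_contact_gap():
    verdict = community_persistence([0, 300], (0, 365), bridging_intervals=[(50, 250)])
    assert verdict.persistent


def test_community_persistence_matches_oracle_on_random_streams():
    rng = np.random.default_rng(123)
    for _ in range(300):
        days = sorted(int(d) for d in rng.integers(0, 365, size=rng.integers(0, 15)))
        bridges = []
        for _ in range(int(rng.integers(0, 3))):
            s = int(rng.integers(0, 340))
            bridges.append((s, s + int(rng.integers(1, 80))))
        w1 = int(rng.integers(30, 366))
        got = community_persistence(days, (0, w1), bridges)
        assert got.persistent == oracle_community_persistent(days, (0, w1), bridges)
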