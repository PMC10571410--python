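"""Drug-exposure episodes and persistence of care.

Dispensation records carry only a date and a quantity expressed in defined
daily doses (DDD); one DDD is taken to supply one day of treatment.  Episodes
of continuous exposure are assembled by chaining prescriptions whose
end-of-supply to start-of-next interval is shorter than a gap threshold
(default 90 days); a gap at least that long closes the episode and, inside a
follow-up window, marks discontinuation.  Community care follows the same
logic with outpatient contacts in place of drug supply: a patient is
persistent when no 90-day stretch of follow-up passes without a contact.
Days spent in hospital or in a residential facility count as covered time for
both notions of persistence (continuity of care is maintained by the
facility), which lets an admission bridge what would otherwise be a
disqualifying gap.

All functions here work on integer day offsets (e.g. ``date.toordinal()``),
keeping them independent of calendar handling and cheap to brute-force in
tests.  Windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

DEFAULT_GAP_DAYS = 90

Interval = tuple[int, int]  # inclusive (first_day, last_day)


@dataclass(frozen=True)
class TreatmentEpisode:
    """A maximal run of consecutive prescriptions for one patient and class.

    ``start_day``/``end_day`` bound the supplied time (inclusive);
    ``covered_days`` counts days actually supplied, which can be smaller than
    the span when consecutive prescriptions leave short (< gap) holes.
    """

    start_day: int
    end_day: int
    n_dispensations: int
    covered_days: int

    @property
    def span_days(self) -> int:
        return self.end_day - self.start_day + 1


@dataclass(frozen=True)
class PersistenceVerdict:
    """Outcome of a persistence assessment over a follow-up window."""

    persistent: bool
    first_gap_start: Optional[int] = None


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of inclusive integer intervals, sorted and disjoint."""
    merged: list[Interval] = []
    for s, e in sorted(intervals):
        if e < s:
            continue
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_episodes(
    dispensations: Iterable[tuple[int, float]],
    gap_days: int = DEFAULT_GAP_DAYS,
    carryover: bool = True,
) -> list[TreatmentEpisode]:
    """Chain one patient's dispensations of one drug class into episodes.

    Parameters
    ----------
    dispensations
        ``(day, n_ddd)`` pairs; sorted internally, non-positive quantities
        are dropped.  Each dispensation supplies ``ceil(n_ddd)`` days.
    gap_days
        Two prescriptions are consecutive when the interval from the end of
        supply of the first to the start of the second is strictly below
        this threshold; an interval of exactly ``gap_days`` already breaks
        the chain.
    carryover
        When supply overlaps (a refill collected early), shift the new
        supply forward to start after the current stock runs out
        (stockpiling).  When off, overlapping days are simply lost.
    """
    rows = sorted((d, q) for d, q in dispensations if q > 0)
    episodes: list[TreatmentEpisode] = []
    raw: list[Interval] = []  # supply intervals of the open episode
    cur_end = None  # last supplied day of the open episode
    n_disp = 0

    def close() -> None:
        nonlocal raw, cur_end, n_disp
        if not raw:
            return
        merged = _merge_intervals(raw)
        covered = sum(e - s + 1 for s, e in merged)
        episodes.append(
            TreatmentEpisode(
                start_day=merged[0][0],
                end_day=merged[-1][1],
                n_dispensations=n_disp,
                covered_days=covered,
            )
        )
        raw, cur_end, n_disp = [], None, 0

    for day, q in rows:
        duration = math.ceil(q)
        if cur_end is not None and day - cur_end >= gap_days:
            close()
        if cur_end is None:
            start = day
        elif carryover:
            start = max(day, cur_end + 1)
        else:
            start = day
        end = start + duration - 1
        raw.append((start, end))
        cur_end = end if cur_end is None else max(cur_end, end)
        n_disp += 1
    close()
    return episodes


def _chain_end(blocks: Sequence[Interval], anchor: int, gap_days: int) -> int:
    """Last covered day reachable from the block containing ``anchor`` by
    hopping gaps strictly shorter than ``gap_days``."""
    idx = next(i for i, (s, e) in enumerate(blocks) if s <= anchor <= e)
    end = blocks[idx][1]
    for s, e in blocks[idx + 1 :]:
        if s - end >= gap_days:
            break
        end = e
    return end


def drug_persistence(
    dispensations: Iterable[tuple[int, float]],
    window: tuple[int, int],
    bridging_intervals: Iterable[Interval] = (),
    gap_days: int = DEFAULT_GAP_DAYS,
    carryover: bool = True,
) -> Optional[PersistenceVerdict]:
    """Judge persistence with a drug class over a follow-up window.

    The patient enters the assessment at their first dispensation inside
    ``window`` (returns ``None`` when there is none: not in the denominator).
    They are persistent when the supply chain containing that dispensation —
    merging across sub-threshold gaps and counting hospital/residential days
    (``bridging_intervals``) as covered — extends close enough to the end of
    the window that no ``gap_days``-long uncovered stretch ever occurs.
    """
    w_start, w_end = window
    rows = sorted((d, q) for d, q in dispensations if q > 0)
    first_in_window = next((d for d, _ in rows if w_start <= d < w_end), None)
    if first_in_window is None:
        return None
    supply = [
        (ep.start_day, ep.end_day)
        for ep in build_episodes(rows, gap_days=gap_days, carryover=carryover)
    ]
    blocks = _merge_intervals(list(supply) + list(bridging_intervals))
    end = _chain_end(blocks, first_in_window, gap_days)
    # discontinued when a full refill-free interval elapses while the
    # patient is still under observation: persistent supply must reach into
    # the final gap_days - 1 days of the window
    if (w_end - 1) - end >= gap_days:
        return PersistenceVerdict(persistent=False, first_gap_start=end + 1)
    return PersistenceVerdict(persistent=True)


def community_persistence(
    contact_days: Iterable[int],
    window: tuple[int, int],
    bridging_intervals: Iterable[Interval] = (),
    gap_days: int = DEFAULT_GAP_DAYS,
) -> PersistenceVerdict:
    """Judge persistence with community care over a follow-up window.

    Covered days are outpatient-contact days plus hospital/residential days;
    the patient is persistent when every maximal uncovered stretch inside
    the window (including before the first contact and after the last) is
    strictly shorter than ``gap_days``.
    """
    w_start, w_end = window
    covered = _merge_intervals(
        [(d, d) for d in contact_days] + list(bridging_intervals)
    )
    # clip to window
    clipped = [
        (max(s, w_start), min(e, w_end - 1))
        for s, e in covered
        if e >= w_start and s < w_end
    ]
    cursor = w_start  # first day of the current uncovered run
    for s, e in clipped:
        if s - cursor >= gap_days:
            return PersistenceVerdict(persistent=False, first_gap_start=cursor)
        cursor = e + 1
    if w_end - cursor >= gap_days:
        return PersistenceVerdict(persistent=False, first_gap_start=cursor)
    return PersistenceVerdict(persistent=True)
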