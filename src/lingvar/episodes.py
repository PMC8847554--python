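"""Recoding of self-reported depressed intervals into analysis calendars.

Raw reports are noisy: intervals may overlap, sit back to back, or describe
sub-threshold stretches. The recoding contract is

* intervals separated by fewer than 14 days are merged (the intervening days
  become part of the episode),
* intervals still shorter than 14 days afterwards are dropped,

with inclusive day counting (``end - start + 1``). The merge step runs before
the drop step by default so that two short adjacent reports that jointly
cover two weeks survive; the reverse order is available via ``merge_first``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DateInterval = tuple[dt.date, dt.date]

#: minimum episode length and minimum gap, in days ("two weeks")
MIN_EPISODE_DAYS = 14
MIN_GAP_DAYS = 14

#: participants could report at most this many episodes
MAX_RAW_EPISODES = 5


def _interval_len(iv: DateInterval) -> int:
    return (iv[1] - iv[0]).days + 1


def _gap_days(a: DateInterval, b: DateInterval) -> int:
    """Days strictly between interval a and a later interval b."""
    return (b[0] - a[1]).days - 1


@dataclass(frozen=True)
class EpisodeCalendar:
    """Non-overlapping, recoded depressed intervals for one user."""

    user_id: str
    intervals: tuple[DateInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev: DateInterval | None = None
        for iv in self.intervals:
            if iv[0] > iv[1]:
                raise ValueError(f"interval {iv} has start after end")
            if _interval_len(iv) < MIN_EPISODE_DAYS:
                raise ValueError(f"interval {iv} shorter than {MIN_EPISODE_DAYS} days")
            if prev is not None:
                if iv[0] <= prev[1]:
                    raise ValueError("intervals not sorted/non-overlapping")
                if _gap_days(prev, iv) < MIN_GAP_DAYS:
                    raise ValueError(f"gap between {prev} and {iv} below {MIN_GAP_DAYS} days")
            prev = iv

    @property
    def total_days(self) -> int:
        return sum(_interval_len(iv) for iv in self.intervals)

    def contains(self, day: dt.date) -> bool:
        return any(a <= day <= b for a, b in self.intervals)


def _merge(intervals: list[DateInterval], max_gap: int) -> list[DateInterval]:
    """Union intervals whose gap (days strictly between) is <= max_gap."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv[0] <= last[1] or _gap_days(last, iv) <= max_gap:
            merged[-1] = (last[0], max(last[1], iv[1]))
        else:
            merged.append(iv)
    return merged


def recode_episodes(
    raw_intervals: list[DateInterval],
    user_id: str = "",
    merge_first: bool = True,
) -> EpisodeCalendar:
    """Recode raw self-reported intervals into an :class:`EpisodeCalendar`.

    Overlapping or near-adjacent reports (gap <= 13 days) are unioned; what
    remains shorter than 14 days is recoded "not depressed" and removed.
    Idempotent: recoding a recoded calendar changes nothing.
    """
    for iv in raw_intervals:
        if iv[0] > iv[1]:
            raise ValueError(f"interval {iv} has start after end")
    if merge_first:
        merged = _merge(list(raw_intervals), MIN_GAP_DAYS - 1)
        kept = [iv for iv in merged if _interval_len(iv) >= MIN_EPISODE_DAYS]
    else:
        kept = [iv for iv in raw_intervals if _interval_len(iv) >= MIN_EPISODE_DAYS]
        kept = _merge(kept, MIN_GAP_DAYS - 1)
    return EpisodeCalendar(user_id=user_id, intervals=tuple(kept))


def label_days(calendar: EpisodeCalendar, matrix) -> np.ndarray:
    """Boolean per-row labels for a feature matrix: True = within an episode.

    Interval bounds are closed on both sides, so a day equal to an interval
    end is "within".
    """
    return np.array([calendar.contains(d) for d in matrix.dates], dtype=bool)


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    n_total: int
    n_within: int
    n_outside: int


def check_eligibility(matrix, labels: np.ndarray | None = None, mode: str = "overall",
                      min_days_overall: int = 30, min_days_paired: int = 15) -> Eligibility:
    """Apply the day-count eligibility filters.

    ``overall`` requires at least 30 observed days in total; ``paired``
    requires at least 15 observed days both within and outside an episode.
    """
    n_total = matrix.n_days
    if labels is None:
        labels = np.zeros(n_total, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != n_total:
        raise ValueError("labels do not cover the matrix days")
    n_within = int(labels.sum())
    n_outside = n_total - n_within
    if mode == "overall":
        ok = n_total >= min_days_overall
    elif mode == "paired":
        ok = n_within >= min_days_paired and n_outside >= min_days_paired
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Eligibility(eligible=ok, n_total=n_total, n_within=n_within, n_outside=n_outside)


# ---------------------------------------------------------------------------
# CSV I/O


def read_episode_csv(path) -> dict[str, list[DateInterval]]:
    """Read raw episode reports (user_id, start_date, end_date; ISO-8601).

    Users reporting more than five intervals keep the five earliest starts;
    extras are dropped with a warning.
    """
    df = pd.read_csv(path, dtype={"user_id": str})
    out: dict[str, list[DateInterval]] = {}
    for uid, grp in df.groupby("user_id"):
        ivs = sorted(
            (dt.date.fromisoformat(str(r.start_date)), dt.date.fromisoformat(str(r.end_date)))
            for r in grp.itertuples()
        )
        if len(ivs) > MAX_RAW_EPISODES:
            log.warning("user %s reported %d episodes; keeping the first %d",
                        uid, len(ivs), MAX_RAW_EPISODES)
            ivs = ivs[:MAX_RAW_EPISODES]
        out[str(uid)] = ivs
    return out


def write_calendar_csv(calendars: list[EpisodeCalendar], path) -> None:
    rows = [
        {"user_id": c.user_id, "start_date": a.isoformat(), "end_date": b.isoformat()}
        for c in calendars
        for a, b in c.intervals
    ]
    pd.DataFrame(rows, columns=["user_id", "start_date", "end_date"]).to_csv(path, index=False)
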