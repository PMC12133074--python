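"""Pandemic phase calendar: weekday date -> (subphase, season, days-in-phase).

The study window 2019-2021 is partitioned into a prepandemic baseline (phase 0)
and 12 pandemic subphases delimited by ISO-8601 week numbers (restrictive
measures define the main phases, national infection-rate turning points the
subphases). Every weekday maps to exactly one subphase; the within-subphase
clock ``t_days`` counts calendar days since the subphase's first weekday and is
the time variable of the segmented regression.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping

import pandas as pd

from .config import (
    ConfigurationError,
    DEFAULT_PHASE_SPEC,
    STUDY_END,
    STUDY_START,
)

__all__ = ["season_of", "build_phase_calendar", "subphase_spans", "weekdays"]


def season_of(date: dt.date) -> str:
    """Meteorological season: winter Dec-Feb, spring Mar-May, summer Jun-Aug,
    autumn Sep-Nov."""
    m = date.month
    if m in (12, 1, 2):
        return "winter"
    if m in (3, 4, 5):
        return "spring"
    if m in (6, 7, 8):
        return "summer"
    return "autumn"


def weekdays(start: dt.date, end: dt.date) -> list[dt.date]:
    """All Monday-Friday dates in [start, end]."""
    out = []
    d = start
    one = dt.timedelta(days=1)
    while d <= end:
        if d.weekday() < 5:
            out.append(d)
        d += one
    return out


def build_phase_calendar(
    phase_spec: Mapping[str, Iterable[tuple[int, int, int]]] | None = None,
    start: dt.date = STUDY_START,
    end: dt.date = STUDY_END,
) -> pd.DataFrame:
    """Map every weekday in [start, end] to a subphase and season.

    ``phase_spec`` maps subphase id -> spans of (iso_year, first_week,
    last_week), inclusive in ISO-8601 week numbering (2020 has 53 weeks).
    Dates are assigned through their own ISO year/week, so e.g. 2019-12-30
    (ISO 2020-W01) falls in the span covering 2020 week 1.

    Returns a DataFrame with columns ``date``, ``subphase``, ``season``,
    ``t_days`` (calendar days since the subphase's first weekday).

    Raises :class:`ConfigurationError` on overlapping spans or weekdays not
    covered by any span, listing the offending ISO weeks.
    """
    spec = dict(phase_spec) if phase_spec is not None else dict(DEFAULT_PHASE_SPEC)
    if end < start:
        raise ConfigurationError("calendar range is empty")

    week_map: dict[tuple[int, int], str] = {}
    overlaps: list[tuple[int, int]] = []
    for sub, spans in spec.items():
        for year, w0, w1 in spans:
            if w1 < w0:
                raise ConfigurationError(
                    f"subphase {sub}: week span {w0}-{w1} of {year} is empty")
            for w in range(w0, w1 + 1):
                key = (year, w)
                if key in week_map and week_map[key] != sub:
                    overlaps.append(key)
                week_map[key] = sub
    if overlaps:
        raise ConfigurationError(f"overlapping phase spec weeks: {sorted(set(overlaps))}")

    rows = []
    gaps: set[tuple[int, int]] = set()
    for d in weekdays(start, end):
        iso = d.isocalendar()
        key = (iso.year, iso.week)
        sub = week_map.get(key)
        if sub is None:
            gaps.add(key)
            continue
        rows.append((d, sub, season_of(d)))
    if gaps:
        raise ConfigurationError(f"phase spec leaves ISO weeks uncovered: {sorted(gaps)}")

    cal = pd.DataFrame(rows, columns=["date", "subphase", "season"])
    first = cal.groupby("subphase")["date"].transform("min")
    cal["t_days"] = (pd.to_datetime(cal["date"]) - pd.to_datetime(first)).dt.days
    return cal


def subphase_spans(calendar: pd.DataFrame) -> dict[str, int]:
    """Span in calendar days (max t_days) per subphase."""
    return calendar.groupby("subphase")["t_days"].max().to_dict()
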