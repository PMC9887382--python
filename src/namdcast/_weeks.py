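"""ISO-week arithmetic for contiguous weekly series.

Weeks are (iso_year, iso_week) pairs; contiguity is defined by the ISO-8601
calendar (52- and 53-week years handled by ``datetime.date.fromisocalendar``).
"""

from __future__ import annotations

import datetime as _dt

Week = tuple[int, int]


def week_monday(week: Week) -> _dt.date:
    """Monday of an ISO week; raises ValueError for an invalid week number."""
    year, num = week
    return _dt.date.fromisocalendar(year, num, 1)


def next_week(week: Week) -> Week:
    iso = (week_monday(week) + _dt.timedelta(weeks=1)).isocalendar()
    return (iso.year, iso.week)


def week_range(start: Week, end: Week) -> list[Week]:
    """Inclusive range of contiguous ISO weeks from start to end."""
    if week_monday(start) > week_monday(end):
        raise ValueError(f"week range start {start} is after end {end}")
    out = [start]
    while out[-1] != end:
        out.append(next_week(out[-1]))
    return out


def is_contiguous(weeks: list[Week]) -> bool:
    return all(next_week(a) == b for a, b in zip(weeks, weeks[1:]))


def parse_week(text: str) -> Week:
    """Parse '2020-W12' (or '2020-12') into an (iso_year, iso_week) pair."""
    year_s, _, week_s = text.partition("-")
    week_s = week_s.lstrip("Ww")
    week = (int(year_s), int(week_s))
    week_monday(week)  # validate
    return week
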