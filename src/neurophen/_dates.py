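"""Calendar helpers shared across the pipeline.

All ages are calendar ("birthday-anniversary") ages: a child born on 29
February has their anniversary on 1 March in non-leap years (roll-forward
convention), so every anniversary is a real date and completed-years ages
are well defined for every (birth, event) pair.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

__all__ = [
    "anniversary",
    "anniversary_series",
    "age_in_years",
    "age_in_years_series",
    "academic_year_start",
    "academic_year_start_series",
    "academic_year_label",
]


def anniversary(birth_date: dt.date, years: int) -> dt.date:
    """The ``years``-th birthday; 29 Feb rolls forward to 1 Mar."""
    birth_date = _as_date(birth_date)
    try:
        return birth_date.replace(year=birth_date.year + years)
    except ValueError:  # 29 Feb in a non-leap target year
        return dt.date(birth_date.year + years, 3, 1)


def anniversary_series(birth_dates: pd.Series, years: int) -> pd.Series:
    """Vectorised :func:`anniversary` for a datetime64 series."""
    bd = pd.to_datetime(birth_dates)
    out = pd.to_datetime(
        {"year": bd.dt.year + years, "month": bd.dt.month, "day": bd.dt.day},
        errors="coerce",
    )
    rolled = pd.to_datetime(
        {"year": bd.dt.year + years, "month": 3, "day": 1}, errors="coerce"
    )
    out = out.where(out.notna(), rolled)
    out.index = birth_dates.index
    return out


def age_in_years(birth_date: dt.date, event_date: dt.date) -> int:
    """Completed calendar years between birth and event (event >= birth)."""
    birth_date, event_date = _as_date(birth_date), _as_date(event_date)
    if event_date < birth_date:
        raise ValueError(f"event_date {event_date} precedes birth_date {birth_date}")
    k = event_date.year - birth_date.year
    if anniversary(birth_date, k) > event_date:
        k -= 1
    return k


def age_in_years_series(birth_dates: pd.Series, event_dates: pd.Series) -> pd.Series:
    bd = pd.to_datetime(birth_dates)
    ev = pd.to_datetime(event_dates)
    k = (ev.dt.year - bd.dt.year).astype("int64")
    ann = pd.to_datetime(
        {"year": bd.dt.year + k, "month": bd.dt.month, "day": bd.dt.day},
        errors="coerce",
    )
    rolled = pd.to_datetime({"year": bd.dt.year + k, "month": 3, "day": 1})
    ann = ann.where(ann.notna(), rolled)
    ann.index = bd.index
    return (k - (ann > ev).astype("int64")).astype("int64")


def academic_year_start(date: dt.date) -> int:
    """Starting calendar year of the academic year (1 Sep–31 Aug) holding ``date``."""
    date = _as_date(date)
    return date.year if date.month >= 9 else date.year - 1


def academic_year_start_series(dates: pd.Series) -> pd.Series:
    d = pd.to_datetime(dates)
    return d.dt.year.where(d.dt.month >= 9, d.dt.year - 1).astype("int64")


def academic_year_label(start_year: int) -> str:
    """``2003 -> "2003/04"``."""
    return f"{start_year}/{(start_year + 1) % 100:02d}"


def _as_date(value) -> dt.date:
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, (str, np.datetime64)):
        return pd.Timestamp(value).date()
    raise TypeError(f"not a date: {value!r}")
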