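"""Solar ephemeris, legal hunting window, and daily bout assignment.

Sunrise/sunset and nautical twilight are computed from the standard NOAA
solar-position equations (geometric mean longitude, equation of time,
declination, hour angle), with one refinement iteration so that the Julian
century is evaluated at the event time itself.  Sunrise and sunset use the
conventional apparent-horizon zenith of 90.833 deg (solar elevation
-0.833 deg, refraction plus solar radius); the nautical twilight boundaries
use 96 deg and 102 deg (elevation -6 deg and -12 deg).

The Swedish legal bear-hunting window runs from one hour before sunrise to
two hours before sunset; the window bounds are reported rounded to a
configurable grid (default 30 min) as regulation times are quoted on the
half hour.

The day is split into two 12-h activity bouts (morning/afternoon) at the
midday minimum of foraging activity, by default 10:00 local time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, time, timedelta

__all__ = [
    "SolarTimes",
    "HuntingWindow",
    "UndefinedSolarEvent",
    "solar_times",
    "hunting_window",
    "assign_bout",
    "twilight_periods",
    "solar_table",
]

# Zenith angles (degrees) of the events we compute.
ZENITH_OFFICIAL = 90.833  # apparent sunrise/sunset
ZENITH_NAUTICAL = 102.0  # sun 12 deg below horizon
ZENITH_CIVIL_TO_NAUTICAL = 96.0  # sun 6 deg below horizon (nautical start)


class UndefinedSolarEvent(ValueError):
    """Raised when a solar event does not occur (polar day or night)."""


@dataclass(frozen=True)
class SolarTimes:
    """Solar event times (local clock) for one date at one site.

    ``daylength_hours`` is sunset minus sunrise in hours.
    """

    date: Date
    sunrise: datetime
    sunset: datetime
    nautical_dawn_start: datetime
    nautical_dusk_end: datetime
    daylength_hours: float


@dataclass(frozen=True)
class HuntingWindow:
    """Legal hunting window for one date: [start, end], local clock."""

    start: datetime
    end: datetime

    @property
    def length_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


def _julian_day(d: Date) -> float:
    """Julian day number at 00:00 UT for a calendar date."""
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def _sun_geometry(t: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (degrees).

    ``t`` is the Julian century from J2000.0.
    """
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * t)
    lam = true_long - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(omega)
    eps_rad = math.radians(eps)
    decl = math.degrees(math.asin(math.sin(eps_rad) * math.sin(math.radians(lam))))
    y = math.tan(eps_rad / 2.0) ** 2
    l0r = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * ecc * math.sin(mrad)
        + 4.0 * ecc * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mrad)
    )
    return eqtime, decl


def _hour_angle(lat: float, decl: float, zenith: float) -> float:
    """Hour angle (degrees) at which the sun reaches ``zenith``.

    Raises :class:`UndefinedSolarEvent` if the sun never reaches that zenith
    on this date (polar day/night for the requested event).
    """
    lat_r, decl_r = math.radians(lat), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(zenith)) / (math.cos(lat_r) * math.cos(decl_r))
        - math.tan(lat_r) * math.tan(decl_r)
    )
    # grazing events: when the sun's extreme elevation touches the target
    # within numerical precision, pin the event to the culmination instead
    # of failing; genuinely unreachable zeniths still raise
    tol = 5e-3
    if cos_ha > 1.0 + tol or cos_ha < -1.0 - tol:
        raise UndefinedSolarEvent(
            f"sun does not cross zenith {zenith} deg at latitude {lat} on this date"
        )
    return math.degrees(math.acos(min(1.0, max(-1.0, cos_ha))))


def _event_minutes_utc(lat: float, lon: float, d: Date, zenith: float, rising: bool) -> float:
    """Minutes after 00:00 UT of a rising/setting event, with one refinement."""
    jd0 = _julian_day(d)
    minutes = 720.0 - 4.0 * lon  # first guess: local solar noon
    for _ in range(2):
        t = (jd0 + minutes / 1440.0 - 2451545.0) / 36525.0
        eqtime, decl = _sun_geometry(t)
        ha = _hour_angle(lat, decl, zenith)
        noon = 720.0 - 4.0 * lon - eqtime
        minutes = noon - 4.0 * ha if rising else noon + 4.0 * ha
    return minutes


def _to_local(d: Date, minutes_utc: float, utc_offset: float) -> datetime:
    base = datetime.combine(d, time(0, 0))
    return base + timedelta(minutes=minutes_utc + 60.0 * utc_offset)


def solar_times(lat: float, lon: float, d: Date, utc_offset: float) -> SolarTimes:
    """Compute sunrise, sunset, and nautical twilight bounds for one date.

    Parameters
    ----------
    lat, lon
        Site coordinates in decimal degrees (north/east positive).
    d
        Calendar date (interpreted in the local clock).
    utc_offset
        Local clock offset from UTC in hours (e.g. +2 for CEST).

    Returns
    -------
    SolarTimes
        Event times on the local clock.  If an event does not occur
        (polar day/night), :class:`UndefinedSolarEvent` is raised rather
        than clamping to midnight.
    """
    sunrise = _to_local(d, _event_minutes_utc(lat, lon, d, ZENITH_OFFICIAL, True), utc_offset)
    sunset = _to_local(d, _event_minutes_utc(lat, lon, d, ZENITH_OFFICIAL, False), utc_offset)
    dawn = _to_local(d, _event_minutes_utc(lat, lon, d, ZENITH_NAUTICAL, True), utc_offset)
    dusk = _to_local(d, _event_minutes_utc(lat, lon, d, ZENITH_NAUTICAL, False), utc_offset)
    daylength = (sunset - sunrise).total_seconds() / 3600.0
    return SolarTimes(
        date=d,
        sunrise=sunrise,
        sunset=sunset,
        nautical_dawn_start=dawn,
        nautical_dusk_end=dusk,
        daylength_hours=daylength,
    )


def _round_to_grid(dt: datetime, grid_minutes: int) -> datetime:
    """Round a datetime to the nearest grid point; exact midpoints round up."""
    day0 = datetime.combine(dt.date(), time(0, 0))
    m = (dt - day0).total_seconds() / 60.0
    rounded = math.floor(m / grid_minutes + 0.5) * grid_minutes
    return day0 + timedelta(minutes=rounded)


def hunting_window(st: SolarTimes, round_to: int = 30) -> HuntingWindow:
    """Legal hunting window: sunrise - 1 h to sunset - 2 h, rounded.

    ``round_to`` is the rounding grid in minutes (half-up at midpoints);
    pass ``round_to=1`` for effectively unrounded bounds.  The unrounded
    window length equals daylength minus one hour.
    """
    start = _round_to_grid(st.sunrise - timedelta(hours=1), round_to)
    end = _round_to_grid(st.sunset - timedelta(hours=2), round_to)
    if end <= start:
        raise ValueError(
            f"degenerate hunting window on {st.date}: start {start} >= end {end}"
        )
    return HuntingWindow(start=start, end=end)


def assign_bout(ts: datetime | time, split_hour: float = 10.0, width_hours: float = 12.0) -> str:
    """Assign a timestamp to the morning or afternoon activity bout.

    The afternoon bout is the half-open interval [split, split + width) on
    the clock face; the morning bout is the complementary wrap-around
    interval.  With the defaults (split 10:00, width 12 h) the morning bout
    runs 22:00-10:00 and the afternoon bout 10:00-22:00, so every instant of
    the day belongs to exactly one bout.
    """
    if isinstance(ts, datetime):
        ts = ts.time()
    h = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    if (h - split_hour) % 24.0 < width_hours:
        return "afternoon"
    return "morning"


def twilight_periods(st: SolarTimes) -> tuple[tuple[datetime, datetime], tuple[datetime, datetime]]:
    """Morning and evening twilight intervals.

    Returns ``([nautical_dawn_start, sunrise), [sunset, nautical_dusk_end))``
    — the periods when the sun is between 12 deg below the horizon and the
    apparent horizon.
    """
    return (
        (st.nautical_dawn_start, st.sunrise),
        (st.sunset, st.nautical_dusk_end),
    )


def solar_table(lat: float, lon: float, dates, utc_offset: float):
    """Per-date solar events as a pandas DataFrame (one row per date)."""
    import pandas as pd

    rows = []
    for d in dates:
        st = solar_times(lat, lon, d, utc_offset)
        win = hunting_window(st)
        rows.append(
            {
                "date": d,
                "sunrise": st.sunrise,
                "sunset": st.sunset,
                "nautical_dawn_start": st.nautical_dawn_start,
                "nautical_dusk_end": st.nautical_dusk_end,
                "daylength_hours": st.daylength_hours,
                "window_start": win.start,
                "window_end": win.end,
            }
        )
    return pd.DataFrame(rows)
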