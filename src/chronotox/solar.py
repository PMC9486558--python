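"""Apparent solar time and solar geometry for treatment-site geography.

Radiotherapy fraction times are recorded as local civil clock times.  The
circadian exposure of interest is the position of the sun, so every fraction
time is converted to *apparent solar time*: solar noon is the moment the sun
crosses the site's meridian.  The conversion removes the time-zone and
daylight-saving offsets, adds the longitude correction (4 minutes per degree
east) and the equation of time (the seasonal difference between apparent and
mean solar time caused by the Earth's orbital eccentricity and axial tilt).

Solar position quantities (declination, equation of time) use the NOAA
low-precision fractional-year equations, accurate to well under a minute for
contemporary dates.  Day length uses the standard sunrise/sunset zenith of
90.833 degrees (atmospheric refraction plus the solar semidiameter).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "GeoSite",
    "LocalTimestamp",
    "solar_declination",
    "equation_of_time",
    "local_to_solar",
    "day_length",
    "max_solar_elevation",
    "eu_dst_active",
]

#: zenith angle of the sun's centre at sunrise/sunset (degrees)
SUNRISE_ZENITH = 90.833


@dataclass(frozen=True)
class GeoSite:
    """A recruiting centre's geography and civil clock rules.

    Parameters
    ----------
    name : str
        Site identifier.
    latitude : float
        Degrees north (decimal).
    longitude : float
        Degrees east (decimal, positive east).
    utc_base_offset : float
        Hours east of UTC in winter (standard time).
    dst_offset : float
        Additional hours during the daylight-saving period (0 or 1).
    dst_rule : str
        ``"eu"`` for the EU calendar (last Sunday of March to last Sunday
        of October) or ``"none"``.
    """

    name: str
    latitude: float
    longitude: float
    utc_base_offset: float
    dst_offset: float = 1.0
    dst_rule: str = "eu"

    def __post_init__(self) -> None:
        if not abs(self.latitude) <= 90:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not (-180 < self.longitude <= 180):
            raise ValueError(f"longitude {self.longitude} outside (-180, 180]")
        if not (-12 <= self.utc_base_offset <= 14):
            raise ValueError(f"utc_base_offset {self.utc_base_offset} outside [-12, 14]")
        if self.dst_offset not in (0, 1):
            raise ValueError("dst_offset must be 0 or 1")
        if self.dst_rule not in ("eu", "none"):
            raise ValueError(f"unknown dst_rule {self.dst_rule!r}")

    def utc_offset(self, date: _dt.date) -> float:
        """Civil clock offset from UTC (hours) on ``date``."""
        if self.dst_rule == "eu" and eu_dst_active(date):
            return self.utc_base_offset + self.dst_offset
        return self.utc_base_offset


@dataclass(frozen=True)
class LocalTimestamp:
    """A local civil date-time at a site.

    ``clock_time`` is decimal hours in [0, 24).  ``utc_offset`` may be given
    explicitly (e.g. from source records); it then takes precedence over the
    site's DST rule.
    """

    date: _dt.date
    clock_time: float
    site: GeoSite
    utc_offset: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.clock_time < 24):
            raise ValueError(f"clock_time {self.clock_time} outside [0, 24)")


def _last_sunday(year: int, month: int) -> _dt.date:
    d = _dt.date(year, month + 1, 1) - _dt.timedelta(days=1) if month < 12 else _dt.date(year, 12, 31)
    return d - _dt.timedelta(days=(d.weekday() + 1) % 7)


def eu_dst_active(date: _dt.date) -> bool:
    """Whether EU summer time is in force on ``date`` (date granularity).

    The EU rule switches at 01:00 UTC on the last Sundays of March and
    October; treatment fractions are daytime events, so whole-date
    resolution is used (the switch dates themselves count as summer time
    from March onward and winter time from October onward).
    """
    return _last_sunday(date.year, 3) <= date < _last_sunday(date.year, 10)


def _fractional_year(day_of_year, hour=12.0):
    """NOAA fractional year gamma (radians) at the given hour."""
    day = np.asarray(day_of_year, dtype=float)
    if np.any((day < 1) | (day > 366)):
        raise ValueError("day_of_year outside 1..366")
    return 2.0 * np.pi / 365.0 * (day - 1 + (np.asarray(hour, dtype=float) - 12.0) / 24.0)


def solar_declination(day_of_year) -> float | np.ndarray:
    """Solar declination (degrees) for a day of the year.

    NOAA low-precision series; range is within +/-23.45 degrees.  Accepts
    scalars or arrays.
    """
    g = _fractional_year(day_of_year)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    out = np.degrees(decl)
    return float(out) if np.isscalar(day_of_year) else out


def equation_of_time(day_of_year) -> float | np.ndarray:
    """Equation of time (minutes): apparent minus mean solar time.

    Positive values mean the sundial runs ahead of the clock.  NOAA
    low-precision series; annual range roughly -14 to +16 minutes.
    """
    g = _fractional_year(day_of_year)
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    return float(eot) if np.isscalar(day_of_year) else eot


def local_to_solar(ts: LocalTimestamp) -> float:
    """Convert a local civil timestamp to apparent solar time.

    Returns decimal hours from solar midnight in [0, 24):

        solar = clock - utc_offset + longitude * 4 min/deg + equation_of_time
    """
    offset = ts.utc_offset
    if offset is None:
        offset = ts.site.utc_offset(ts.date)
    doy = ts.date.timetuple().tm_yday
    solar = (
        ts.clock_time
        - offset
        + ts.site.longitude * 4.0 / 60.0
        + equation_of_time(doy) / 60.0
    )
    return float(solar % 24.0)


def local_to_solar_arrays(
    day_of_year: np.ndarray,
    clock_hours: np.ndarray,
    longitude: np.ndarray,
    utc_offset: np.ndarray,
) -> np.ndarray:
    """Vectorised civil-to-solar conversion (all inputs broadcastable arrays).

    ``utc_offset`` must already include any active DST hour.
    """
    solar = (
        np.asarray(clock_hours, dtype=float)
        - np.asarray(utc_offset, dtype=float)
        + np.asarray(longitude, dtype=float) * 4.0 / 60.0
        + equation_of_time(np.asarray(day_of_year)) / 60.0
    )
    return solar % 24.0


def day_length(date: _dt.date | int, latitude: float) -> tuple[float, bool]:
    """Day length in hours for a date (or day of year) and latitude.

    Uses cos H = (sin(-0.833 deg) - sin(lat) sin(decl)) / (cos(lat) cos(decl))
    and returns ``2 H / 15`` hours.  The second return value flags a polar
    day/night degenerate case, for which 24.0 or 0.0 is returned.
    """
    doy = date if isinstance(date, int) else date.timetuple().tm_yday
    decl = np.radians(solar_declination(doy))
    lat = np.radians(latitude)
    cos_h = (np.sin(np.radians(-(SUNRISE_ZENITH - 90.0))) - np.sin(lat) * np.sin(decl)) / (
        np.cos(lat) * np.cos(decl)
    )
    if cos_h <= -1.0:
        return 24.0, True
    if cos_h >= 1.0:
        return 0.0, True
    h = np.degrees(np.arccos(cos_h))
    return float(2.0 * h / 15.0), False


def max_solar_elevation(date: _dt.date | int, latitude: float) -> float:
    """Maximum solar elevation (degrees) at solar noon: 90 - |lat - decl|."""
    doy = date if isinstance(date, int) else date.timetuple().tm_yday
    return float(90.0 - abs(latitude - solar_declination(doy)))


def solar_times_for_fractions(
    site: GeoSite,
    dates: Iterable[_dt.date],
    clock_times: Iterable[float],
    utc_offsets: Iterable[float | None] | None = None,
) -> np.ndarray:
    """Solar times for a patient's fraction schedule at one site."""
    dates = list(dates)
    clock = np.asarray(list(clock_times), dtype=float)
    if utc_offsets is None:
        offs = np.array([site.utc_offset(d) for d in dates], dtype=float)
    else:
        offs = np.array(
            [site.utc_offset(d) if o is None else o for d, o in zip(dates, utc_offsets)],
            dtype=float,
        )
    doy = np.array([d.timetuple().tm_yday for d in dates])
    return local_to_solar_arrays(doy, clock, site.longitude, offs)
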