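"""Sunrise/sunset times and seasonal migration clocks.

Implements the standard NOAA solar-position closed forms (fractional year,
equation of time, solar declination, hour angle at zenith 90.833 deg).
Clock times are local *standard* time: a fixed UTC offset with no daylight
saving, since only durations and relative timing matter to the migration
model and a fixed offset keeps runs reproducible.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import math
from dataclasses import dataclass

from .exceptions import UnsupportedLatitudeError

#: Fixed season -> month mapping (meteorological quarters).
SEASON_MONTHS = {
    "JFM": (1, 2, 3),
    "AMJ": (4, 5, 6),
    "JAS": (7, 8, 9),
    "OND": (10, 11, 12),
}

_ZENITH_DEG = 90.833  # official sunrise/sunset zenith (refraction + solar disc)


@dataclass(frozen=True)
class SeasonSpec:
    """A season of the simulation and the location used for its solar clock.

    Defaults are a Northwest Atlantic site (42.35 N, 71.05 W) in 2019 with
    clock times in UTC-5 standard time.
    """

    season: str
    year: int = 2019
    latitude: float = 42.35
    longitude: float = -71.05
    utc_offset: float = -5.0

    def __post_init__(self):
        if self.season not in SEASON_MONTHS:
            raise ValueError(f"unknown season {self.season!r}; "
                             f"expected one of {sorted(SEASON_MONTHS)}")

    @property
    def months(self) -> tuple[int, int, int]:
        return SEASON_MONTHS[self.season]


def _solar_angles(date: _dt.date, hour: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    doy = date.timetuple().tm_yday
    ndays = 366 if calendar.isleap(date.year) else 365
    g = 2.0 * math.pi / ndays * (doy - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075
                       + 0.001868 * math.cos(g) - 0.032077 * math.sin(g)
                       - 0.014615 * math.cos(2 * g) - 0.040849 * math.sin(2 * g))
    decl = (0.006918
            - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
            - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
            - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))
    return eqtime, decl


def solar_events(date: _dt.date, spec: SeasonSpec) -> tuple[float, float]:
    """Sunrise and sunset as local-standard-time hours since midnight.

    Raises
    ------
    UnsupportedLatitudeError
        Poleward of 66.5 degrees, where polar day/night would require
        special-casing that this model does not need.
    """
    lat = spec.latitude
    if abs(lat) >= 66.5:
        raise UnsupportedLatitudeError(
            f"latitude {lat} is inside a polar circle; not supported")
    eqtime, decl = _solar_angles(date, 12.0)
    lat_r = math.radians(lat)
    cos_ha = (math.cos(math.radians(_ZENITH_DEG))
              / (math.cos(lat_r) * math.cos(decl))
              - math.tan(lat_r) * math.tan(decl))
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha_deg = math.degrees(math.acos(cos_ha))
    # minutes UTC; longitude positive east
    sunrise_utc = 720.0 - 4.0 * (spec.longitude + ha_deg) - eqtime
    sunset_utc = 720.0 - 4.0 * (spec.longitude - ha_deg) - eqtime
    off = spec.utc_offset * 60.0
    return (sunrise_utc + off) / 60.0, (sunset_utc + off) / 60.0


def _season_dates(spec: SeasonSpec):
    for month in spec.months:
        ndays = calendar.monthrange(spec.year, month)[1]
        for day in range(1, ndays + 1):
            yield _dt.date(spec.year, month, day)


def seasonal_migration_times(spec: SeasonSpec) -> tuple[float, float]:
    """Season-mean sunrise and sunset (local hours).

    The migration clock is frozen within a season: the arithmetic mean of
    the daily sunrise and sunset times over all days of the season's three
    months in the given year.
    """
    rises, sets = [], []
    for date in _season_dates(spec):
        r, s = solar_events(date, spec)
        rises.append(r)
        sets.append(s)
    return sum(rises) / len(rises), sum(sets) / len(sets)
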