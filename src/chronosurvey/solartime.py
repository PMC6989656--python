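"""Solar geometry and Standard-Time vs Daylight-Saving-Time arithmetic.

Implements the low-precision NOAA solar equations (fractional-year form):
solar declination and the equation of time from the day of year, then
sunrise/sunset as the crossing of solar altitude through -0.833 degrees
(atmospheric refraction plus the solar half-disc).  Accuracy is about one
minute, which is ample for policy-level statements about local sunrise
clock times.

The social-time comparison is modelled purely through the UTC offset of the
local clock: Central European Standard Time is UTC+1, Daylight Saving Time
UTC+2, applied yearlong; transition dates are out of scope.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "GeoPoint",
    "SolarDay",
    "solar_position",
    "sunrise_sunset",
    "sunrise_gradient",
    "day_of_year",
]

#: Solar altitude (degrees) defining sunrise/sunset.
HORIZON_ALT_DEG = -0.833

ST_OFFSET_H = 1.0   # Central European (Standard) Time
DST_OFFSET_H = 2.0  # Central European Summer Time


@dataclass(frozen=True)
class GeoPoint:
    """A location given as degrees north and degrees east."""

    latitude: float
    longitude: float

    def __post_init__(self):
        if not abs(self.latitude) <= 90:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not abs(self.longitude) <= 180:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class SolarDay:
    """Sunrise/sunset for one date and location, in local clock hours.

    ``polar`` is ``"day"`` or ``"night"`` when the sun never crosses the
    horizon (then the time fields are ``None``), else ``None``.
    """

    date: dt.date
    sunrise: Optional[float]
    sunset: Optional[float]
    solar_noon: Optional[float]
    day_length: Optional[float]
    utc_offset: float
    polar: Optional[str] = None


def day_of_year(date: dt.date) -> int:
    return date.timetuple().tm_yday


def solar_position(date: dt.date, hour_utc: float = 12.0) -> dict:
    """Solar declination (degrees) and equation of time (minutes).

    NOAA low-precision expansion in the fractional year
    ``gamma = 2*pi/365 * (doy - 1 + (hour - 12)/24)``.
    """
    if not 1900 <= date.year <= 2100:
        raise ValueError(f"year {date.year} outside supported range 1900-2100")
    gamma = 2.0 * math.pi / 365.0 * (day_of_year(date) - 1 + (hour_utc - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    return {"declination": math.degrees(decl), "equation_of_time": eqtime}


def sunrise_sunset(point: GeoPoint, date: dt.date, utc_offset: float = ST_OFFSET_H,
                   horizon_alt: float = HORIZON_ALT_DEG) -> SolarDay:
    """Sunrise, sunset, solar noon and day length in local clock hours.

    The local clock is ``UTC + utc_offset`` (ST = +1, DST = +2 in the CET
    zone).  Polar day/night is flagged rather than raising.
    """
    if not -12.0 <= utc_offset <= 14.0:
        raise ValueError(f"utc_offset out of range: {utc_offset}")
    pos = solar_position(date)
    decl = math.radians(pos["declination"])
    lat = math.radians(point.latitude)
    zenith = math.radians(90.0 - horizon_alt)

    cos_ha = (math.cos(zenith) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    noon_utc_min = 720.0 - 4.0 * point.longitude - pos["equation_of_time"]
    noon_local = noon_utc_min / 60.0 + utc_offset
    if cos_ha > 1.0:
        return SolarDay(date, None, None, noon_local, None, utc_offset, polar="night")
    if cos_ha < -1.0:
        return SolarDay(date, None, None, noon_local, 24.0, utc_offset, polar="day")

    ha_deg = math.degrees(math.acos(cos_ha))
    sunrise_utc_min = 720.0 - 4.0 * (point.longitude + ha_deg) - pos["equation_of_time"]
    sunset_utc_min = 720.0 - 4.0 * (point.longitude - ha_deg) - pos["equation_of_time"]
    day_length = (sunset_utc_min - sunrise_utc_min) / 60.0
    return SolarDay(
        date=date,
        sunrise=sunrise_utc_min / 60.0 + utc_offset,
        sunset=sunset_utc_min / 60.0 + utc_offset,
        solar_noon=noon_local,
        day_length=day_length,
        utc_offset=utc_offset,
    )


def sunrise_gradient(p1: GeoPoint, p2: GeoPoint, dates: Iterable[dt.date],
                     utc_offset: float = ST_OFFSET_H) -> float:
    """Mean sunrise difference sunrise(p1) - sunrise(p2) in minutes.

    Averaged over ``dates`` under a common UTC offset; dates where either
    location is in polar day/night are excluded (all-polar input raises).
    At fixed latitude the gradient is close to -4 min per degree of
    eastward longitude.
    """
    diffs = []
    for date in dates:
        d1 = sunrise_sunset(p1, date, utc_offset)
        d2 = sunrise_sunset(p2, date, utc_offset)
        if d1.polar or d2.polar:
            continue
        diffs.append((d1.sunrise - d2.sunrise) * 60.0)
    if not diffs:
        raise ValueError("no non-polar dates to average over")
    return float(np.mean(diffs))
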