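"""Low-precision solar ephemeris (NOAA/Meeus-style) for sun covariates.

Computes the sun's altitude above the horizon and azimuth (from north,
clockwise), both in radians, from a UTC timestamp and an observer's
latitude/longitude. Accuracy of this truncated series is a few
hundredths of a degree over 1900-2100, ample for modelling how sun
position modulates PIR trigger probability. Atmospheric refraction is not
applied.
"""

from __future__ import annotations

import math
from datetime import datetime, timezone

__all__ = ["solar_position"]


def _julian_day(dt: datetime) -> float:
    if dt.tzinfo is not None:
        dt = dt.astimezone(timezone.utc).replace(tzinfo=None)
    year, month = dt.year, dt.month
    day = (dt.day + dt.hour / 24.0 + dt.minute / 1440.0
           + (dt.second + dt.microsecond / 1e6) / 86400.0)
    if month <= 2:
        year -= 1
        month += 12
    a = year // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (year + 4716)) + math.floor(30.6001 * (month + 1)) + day + b - 1524.5


def solar_position(when: datetime, latitude: float, longitude: float) -> tuple[float, float]:
    """Sun altitude and azimuth (radians) at a UTC time and location.

    Parameters
    ----------
    when : datetime
        Timestamp; naive datetimes are taken as UTC. Valid 1900-2100.
    latitude, longitude : float
        Observer position in degrees; longitude positive east.

    Returns
    -------
    (altitude, azimuth) : tuple of float
        Altitude in [-pi/2, pi/2]; azimuth in [0, 2*pi), measured from
        north through east.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude must lie in [-90, 90], got {latitude!r}")
    if not 1900 <= when.year <= 2100:
        raise ValueError(f"timestamp year {when.year} outside the supported 1900-2100 range")

    jd = _julian_day(when)
    T = (jd - 2451545.0) / 36525.0

    # geometric mean longitude and anomaly of the sun (degrees)
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = math.radians(M)
    C = ((1.914602 - T * (0.004817 + 0.000014 * T)) * math.sin(Mr)
         + (0.019993 - 0.000101 * T) * math.sin(2 * Mr)
         + 0.000289 * math.sin(3 * Mr))
    true_long = L0 + C
    omega = math.radians(125.04 - 1934.136 * T)
    lam = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))

    # obliquity of the ecliptic, corrected for nutation (degrees)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.8150 + T * (0.00059 - 0.001813 * T))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))

    decl = math.asin(math.sin(eps) * math.sin(lam))

    # equation of time (minutes)
    y = math.tan(eps / 2.0) ** 2
    L0r = math.radians(L0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * L0r) - 2 * e * math.sin(Mr)
        + 4 * e * y * math.sin(Mr) * math.cos(2 * L0r)
        - 0.5 * y * y * math.sin(4 * L0r) - 1.25 * e * e * math.sin(2 * Mr)
    )

    utc = when if when.tzinfo is None else when.astimezone(timezone.utc)
    minutes = utc.hour * 60.0 + utc.minute + (utc.second + utc.microsecond / 1e6) / 60.0
    true_solar_minutes = (minutes + eot + 4.0 * longitude) % 1440.0
    hour_angle = math.radians(true_solar_minutes / 4.0 - 180.0)  # 0 at solar noon

    lat = math.radians(latitude)
    sin_alt = (math.sin(lat) * math.sin(decl)
               + math.cos(lat) * math.cos(decl) * math.cos(hour_angle))
    altitude = math.asin(max(-1.0, min(1.0, sin_alt)))

    # azimuth from north, clockwise through east
    az_south = math.atan2(
        math.sin(hour_angle),
        math.cos(hour_angle) * math.sin(lat) - math.tan(decl) * math.cos(lat),
    )
    azimuth = (az_south + math.pi) % (2.0 * math.pi)
    return altitude, azimuth
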