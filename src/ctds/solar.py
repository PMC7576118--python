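"""Sunrise/sunset from the NOAA solar-position equations.

Implements the NOAA Solar Calculator spreadsheet equations (Meeus-based),
accurate to about one minute for |latitude| < 66 deg, which is ample for
defining diel activity windows. Times are returned as naive local
standard-time datetimes for a fixed UTC offset: camera-trap clocks in the
field run on a fixed offset, so no DST transitions are applied.
"""

from __future__ import annotations

import datetime as dt
import math

__all__ = ["sunrise_sunset", "UnsupportedLatitudeError"]

# zenith for official sunrise/sunset: 90 deg 50' (refraction + solar radius)
_SUNRISE_ZENITH_DEG = 90.833

_MAX_ABS_LATITUDE = 66.0


class UnsupportedLatitudeError(ValueError):
    """Polar latitudes where the sun may not rise/set are not handled."""


def _julian_day(date: dt.date, hour_utc: float) -> float:
    return date.toordinal() + 1721424.5 + hour_utc / 24.0


def _solar_params(jd: float) -> tuple[float, float]:
    """Return (equation of time in minutes, solar declination in degrees)."""
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)

    m = math.radians(geom_mean_anom)
    eq_of_ctr = (
        math.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_of_ctr
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * math.cos(omega)

    oc = math.radians(obliq_corr)
    decl = math.degrees(math.asin(math.sin(oc) * math.sin(math.radians(app_long))))

    var_y = math.tan(oc / 2.0) ** 2
    l0 = math.radians(geom_mean_long)
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * l0)
        - 2.0 * ecc * math.sin(m)
        + 4.0 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y ** 2 * math.sin(4 * l0)
        - 1.25 * ecc ** 2 * math.sin(2 * m)
    )
    return eqtime, decl


def sunrise_sunset(
    date: dt.date,
    latitude: float,
    longitude: float,
    utc_offset: float,
) -> tuple[dt.datetime, dt.datetime]:
    """Local-clock sunrise and sunset for ``date`` at a site.

    Parameters
    ----------
    date : datetime.date
        Calendar date (local).
    latitude, longitude : float
        Decimal degrees; longitude east-positive (New Mexico is negative).
    utc_offset : float
        Hours the local clock is offset from UTC (e.g. -7 for MST).

    Returns
    -------
    (sunrise, sunset) : naive local datetimes.

    Raises
    ------
    UnsupportedLatitudeError
        For |latitude| >= 66 deg, where the sun may not rise or set.
    """
    if abs(latitude) >= _MAX_ABS_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} outside supported range (|lat| < {_MAX_ABS_LATITUDE})"
        )

    # evaluate equation of time / declination near local solar noon
    jd = _julian_day(date, 12.0 - utc_offset)
    eqtime, decl = _solar_params(jd)

    phi = math.radians(latitude)
    delta = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(_SUNRISE_ZENITH_DEG)) / (math.cos(phi) * math.cos(delta))
        - math.tan(phi) * math.tan(delta)
    )
    if not -1.0 < cos_ha < 1.0:  # pragma: no cover - guarded by latitude check
        raise UnsupportedLatitudeError(
            f"sun does not rise/set on {date} at latitude {latitude}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))

    noon_min = 720.0 - 4.0 * longitude - eqtime + 60.0 * utc_offset
    sunrise_min = noon_min - 4.0 * ha_deg
    sunset_min = noon_min + 4.0 * ha_deg

    base = dt.datetime.combine(date, dt.time())
    return (
        base + dt.timedelta(minutes=sunrise_min),
        base + dt.timedelta(minutes=sunset_min),
    )
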