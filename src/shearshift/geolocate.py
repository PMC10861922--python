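"""Threshold-method light-level geolocation.

Raw illuminance series are turned into daily position fixes: sunrise and
sunset are detected as crossings of a fixed lux threshold (default 10 lx),
longitude follows from the UTC time of local apparent noon (the midpoint of
the two twilights, corrected by the equation of time), and latitude from the
day length given the sun-elevation angle assumed at the crossings (default
-4.5 deg). Fix-level filters (equinox window, speed, bounding box) and the
track-level quality-control rule are applied afterwards.

Near the equinoxes day length is close to 12 h at every latitude, so latitude
is unidentifiable from day length; such fixes carry an ``equinox`` flag and an
undefined latitude. Longitude is unaffected by this degeneracy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "solar_position",
    "solar_declination_rad",
    "equation_of_time_minutes",
    "detect_twilights",
    "position_from_twilights",
    "fixes_from_light",
    "filter_fixes",
    "qc_track",
]


def _fractional_year(times: pd.DatetimeIndex) -> np.ndarray:
    """NOAA fractional-year angle gamma (radians) for UTC timestamps."""
    doy = times.dayofyear.to_numpy(float)
    hour = (
        times.hour.to_numpy(float)
        + times.minute.to_numpy(float) / 60.0
        + times.second.to_numpy(float) / 3600.0
    )
    leap = times.is_leap_year
    ndays = np.where(leap, 366.0, 365.0)
    return 2.0 * np.pi / ndays * (doy - 1.0 + (hour - 12.0) / 24.0)


def solar_declination_rad(times) -> np.ndarray:
    """Solar declination (radians) from the NOAA truncated Fourier series."""
    t = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(times), utc=True))
    g = _fractional_year(t)
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def equation_of_time_minutes(times) -> np.ndarray:
    """Equation of time (apparent minus mean solar time) in minutes."""
    t = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(times), utc=True))
    g = _fractional_year(t)
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def solar_position(times, lon, lat) -> np.ndarray:
    """Solar elevation (degrees) at UTC instant(s) for a given site.

    Low-precision ephemeris (truncated-series declination and equation of
    time); accuracy is about 0.3 deg, ample for threshold geolocation.
    """
    t = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(times), utc=True))
    decl = solar_declination_rad(t)
    eqt = equation_of_time_minutes(t)
    minutes = (
        t.hour.to_numpy(float) * 60.0
        + t.minute.to_numpy(float)
        + t.second.to_numpy(float) / 60.0
        + t.microsecond.to_numpy(float) / 6e7
    )
    tst = minutes + eqt + 4.0 * np.asarray(lon, float)  # true solar time, min
    ha = np.radians(tst / 4.0 - 180.0)
    phi = np.radians(np.asarray(lat, float))
    sin_el = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    el = np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))
    return float(el[0]) if np.ndim(times) == 0 and el.size == 1 else el


# ---------------------------------------------------------------------------
# Twilight detection
# ---------------------------------------------------------------------------


def detect_twilights(light: pd.DataFrame, threshold_lux: float = 10.0) -> pd.DataFrame:
    """Sunrise/sunset pairs from an illuminance series.

    `light` has columns ``timestamp`` (UTC) and ``lux``. A sunrise is an
    upward crossing of the threshold, a sunset a downward crossing, with the
    crossing instant linearly interpolated between samples. Strict
    inequalities are used, so samples exactly at the threshold (plateaus)
    never produce a crossing. Calendar days with anything other than one
    sunrise followed by one sunset are skipped; their dates are recorded in
    ``result.attrs["skipped_days"]``.
    """
    if light.empty:
        raise ValueError("empty light series")
    t = pd.to_datetime(light["timestamp"], utc=True).to_numpy()
    lux = light["lux"].to_numpy(float)
    if t.size >= 2:
        step = (t[1] - t[0]) / np.timedelta64(1, "m")
        if step > 10:
            warnings.warn(
                f"sampling interval {step:.0f} min > 10 min: twilight timing will be coarse"
            )
    l0, l1 = lux[:-1], lux[1:]
    up = (l0 < threshold_lux) & (l1 > threshold_lux)
    down = (l0 > threshold_lux) & (l1 < threshold_lux)
    idx = np.flatnonzero(up | down)
    if idx.size == 0:
        warnings.warn("no threshold crossings found (constant or bounded light)")
    events = []
    for i in idx:
        frac = (threshold_lux - lux[i]) / (lux[i + 1] - lux[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        events.append((tc, "sunrise" if up[i] else "sunset"))
    rows, skipped = [], []
    by_day: dict = {}
    for tc, kind in events:
        by_day.setdefault(pd.Timestamp(tc).date(), []).append((tc, kind))
    for day, evs in sorted(by_day.items()):
        kinds = [k for _, k in evs]
        if kinds == ["sunrise", "sunset"]:
            rows.append({"date": day, "sunrise": evs[0][0], "sunset": evs[1][0]})
        else:
            skipped.append(day)
    out = pd.DataFrame(rows, columns=["date", "sunrise", "sunset"])
    out.attrs["skipped_days"] = skipped
    return out


# ---------------------------------------------------------------------------
# Position inversion
# ---------------------------------------------------------------------------


def position_from_twilights(
    sunrise, sunset, elevation_deg: float = -4.5, refine: bool = True
) -> dict:
    """One daily fix from a sunrise/sunset pair.

    Longitude: local apparent noon is the twilight midpoint; the sun crosses
    the meridian of longitude L at UTC 12h - E - L/15, so
    L = 15 * (12 - E_hours - midpoint_UTC_hours).

    Latitude: the half-day hour angle H (from the pair's duration, 15 deg/h)
    satisfies cos H = (sin a - sin(phi) sin(delta)) / (cos(phi) cos(delta)),
    with a the assumed elevation angle and delta the declination at the
    midpoint; solved for phi by bounded root-finding on (-89, 89). When the
    bracketing function has no sign change (near-equinox degeneracy) the fix
    is emitted with undefined latitude and an ``equinox`` flag.

    The closed form treats declination and the equation of time as constant
    over the day; their drift biases longitude by ~0.1 deg away from the
    solstices. With ``refine`` (default) the closed-form estimate seeds a
    2-equation solve requiring the sun to sit exactly at `elevation_deg` at
    both crossing instants, removing that approximation error.
    """
    sr = pd.Timestamp(sunrise)
    ss = pd.Timestamp(sunset)
    if ss <= sr:
        raise ValueError("sunset must follow sunrise")
    mid = sr + (ss - sr) / 2
    eq_h = float(equation_of_time_minutes(mid)[0]) / 60.0
    mid_h = mid.hour + mid.minute / 60.0 + mid.second / 3600.0 + mid.microsecond / 3.6e9
    lon = 15.0 * (12.0 - eq_h - mid_h)
    lon = ((lon + 180.0) % 360.0) - 180.0

    half_day_h = (ss - sr).total_seconds() / 3600.0 / 2.0
    cos_h = np.cos(np.radians(half_day_h * 15.0))
    delta = float(solar_declination_rad(mid)[0])
    sin_a = np.sin(np.radians(elevation_deg))

    def f(phi_deg):
        phi = np.radians(phi_deg)
        return sin_a - np.sin(phi) * np.sin(delta) - np.cos(phi) * np.cos(delta) * cos_h

    flags = set()
    if f(-89.0) * f(89.0) > 0:
        lat = float("nan")
        flags.add("equinox")
    else:
        lat = brentq(f, -89.0, 89.0, xtol=1e-6)
        if refine:
            lon, lat = _refine_position(sr, ss, lon, lat, elevation_deg)
    return {"date": mid.date(), "lon": float(lon), "lat": float(lat), "flags": flags}


def _refine_position(sr, ss, lon0, lat0, elevation_deg):
    """Solve elevation(t_rise) = elevation(t_set) = a exactly for (lon, lat)."""
    from scipy.optimize import root

    def eqs(x):
        lon, lat = x
        return [
            solar_position(sr, lon, lat) - elevation_deg,
            solar_position(ss, lon, lat) - elevation_deg,
        ]

    sol = root(eqs, [lon0, lat0], method="hybr", tol=1e-10)
    if sol.success and abs(sol.x[0] - lon0) < 2.0 and abs(sol.x[1] - lat0) < 5.0:
        return float(sol.x[0]), float(sol.x[1])
    return lon0, lat0


def fixes_from_light(
    light: pd.DataFrame, threshold_lux: float = 10.0, elevation_deg: float = -4.5
) -> pd.DataFrame:
    """Light series -> daily fixes DataFrame (date, lon, lat, flag)."""
    pairs = detect_twilights(light, threshold_lux)
    rows = []
    for rec in pairs.itertuples(index=False):
        fix = position_from_twilights(rec.sunrise, rec.sunset, elevation_deg)
        rows.append(
            {
                "date": pd.Timestamp(fix["date"]),
                "lon": fix["lon"],
                "lat": fix["lat"],
                "flag": "equinox" if "equinox" in fix["flags"] else "ok",
            }
        )
    return pd.DataFrame(rows, columns=["date", "lon", "lat", "flag"])


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

# nominal equinox dates; day-level precision is all the exclusion window needs
_EQUINOXES = [(3, 20), (9, 22)]


def _near_equinox(dates: pd.Series, window_days: float) -> np.ndarray:
    d = pd.to_datetime(dates)
    near = np.zeros(len(d), dtype=bool)
    for year in d.dt.year.unique():
        for m, dd in _EQUINOXES:
            eq = pd.Timestamp(int(year), m, dd)
            near |= (d - eq).abs().dt.total_seconds().to_numpy() <= window_days * 86400.0
    return near


def filter_fixes(
    fixes: pd.DataFrame,
    equinox_window_days: float = 15.0,
    max_speed_kmh: float = 55.0,
    bbox: tuple = (-22.0, 42.0, 30.0, 60.0),
) -> pd.DataFrame:
    """Apply the three fix-level filters, in this fixed order.

    1. equinox: fixes within +/- `equinox_window_days` of either equinox (and
       any fix with undefined latitude) are flagged ``equinox``;
    2. speed: scanning forward, a fix whose implied speed from the previous
       retained fix exceeds `max_speed_kmh` is flagged ``speed`` and the scan
       re-checks from the same anchor (the later fix of an offending pair is
       removed, iteratively);
    3. bbox: surviving fixes outside (west, east, south, north) are flagged
       ``bbox``.

    Returns a copy with a ``flag`` column; retained fixes have flag ``ok``.
    """
    from .metrics import haversine_km

    out = fixes.sort_values("date").reset_index(drop=True).copy()
    flag = np.array(["ok"] * len(out), dtype=object)
    if "flag" in out.columns:
        flag = out["flag"].to_numpy(object).copy()

    ok = flag == "ok"
    near = _near_equinox(out["date"], equinox_window_days)
    undef = out["lat"].isna().to_numpy()
    flag[ok & (near | undef)] = "equinox"

    t = pd.to_datetime(out["date"]).to_numpy()
    lon = out["lon"].to_numpy(float)
    lat = out["lat"].to_numpy(float)
    anchor = None
    for i in range(len(out)):
        if flag[i] != "ok":
            continue
        if anchor is None:
            anchor = i
            continue
        hours = (t[i] - t[anchor]) / np.timedelta64(1, "h")
        if hours <= 0:
            continue
        speed = haversine_km((lon[anchor], lat[anchor]), (lon[i], lat[i])) / hours
        if speed > max_speed_kmh:
            flag[i] = "speed"
        else:
            anchor = i

    west, east, south, north = bbox
    inside = (lon >= west) & (lon <= east) & (lat >= south) & (lat <= north)
    flag[(flag == "ok") & ~inside] = "bbox"

    out["flag"] = flag
    if not (flag == "ok").any():
        warnings.warn("all fixes removed by filtering")
    return out


def qc_track(
    fixes: pd.DataFrame,
    deployment_start,
    min_fixes: int = 100,
    max_gap_days: float = 61.0,
    window_days: float = 244.0,
) -> tuple[bool, list[str]]:
    """Track-level quality control.

    Rejects tracks with fewer than `min_fixes` retained fixes, or with any
    gap longer than `max_gap_days` between consecutive fixes whose interval
    overlaps [deployment_start, deployment_start + `window_days`].
    """
    kept = fixes[fixes["flag"] == "ok"] if "flag" in fixes.columns else fixes
    reasons = []
    if len(kept) < min_fixes:
        reasons.append(f"too_few_fixes ({len(kept)} < {min_fixes})")
    start = pd.Timestamp(deployment_start)
    end = start + pd.Timedelta(days=window_days)
    d = pd.to_datetime(kept["date"]).sort_values().to_numpy()
    for a, b in zip(d[:-1], d[1:]):
        gap = (b - a) / np.timedelta64(1, "D")
        if gap > max_gap_days and (a <= end.to_numpy()) and (b >= start.to_numpy()):
            reasons.append(f"gap ({gap:.0f} d within the {window_days:.0f}-d window)")
            break
    return (len(reasons) == 0), reasons
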