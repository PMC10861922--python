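"""Migration segmentation.

A migration is detected as the period a bird spends in the Atlantic, on the
far side of a buffer corridor laid across mainland Europe and the Strait of
Gibraltar. Rolling-mean positions are labelled atlantic / mediterranean /
ambiguous against the buffer; ambiguous labels inherit the preceding
unambiguous one (hysteresis), so a crossing is only declared when the
smoothed position falls clearly to one side. The longest Atlantic run is the
core migration; its entry and exit crossings give the departure and return
dates, and the run is split into outbound and return sections at the
latitudinal apex (the fix closest to the 98th percentile of latitude, which
is robust to single extreme-outlier fixes from geolocation error).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape

__all__ = [
    "default_buffer",
    "load_buffer",
    "save_buffer",
    "rolling_positions",
    "label_sides",
    "resolve_ambiguous",
    "find_crossings",
    "core_migration",
    "split_at_apex",
    "segment_track",
    "MigrationBounds",
]

# Corridor across the Strait of Gibraltar and western Europe. South of 36N it
# is a meridional band over the strait; above it slants north-east so France
# stays on the Mediterranean side. Everywhere >= 4 deg of longitude wide
# (>= 222 km even at 60N, above the 170 km minimum) and spans 30-60N
# (~3335 km, above the 555 km minimum).
_DEFAULT_BUFFER_COORDS = [
    (-7.5, 30.0),
    (-3.5, 30.0),
    (-3.5, 36.0),
    (0.5, 60.0),
    (-3.5, 60.0),
    (-7.5, 36.0),
]


def default_buffer() -> Polygon:
    """The packaged Europe/Gibraltar buffer corridor polygon (WGS84)."""
    return Polygon(_DEFAULT_BUFFER_COORDS)


def load_buffer(path) -> Polygon:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]
    geom = gj["geometry"] if gj.get("type") == "Feature" else gj
    return shape(geom)


def save_buffer(polygon: Polygon, path) -> None:
    gj = {"type": "Feature", "properties": {"role": "buffer"}, "geometry": mapping(polygon)}
    with open(path, "w") as fh:
        json.dump(gj, fh)


def rolling_positions(fixes: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Centered rolling-mean longitude and latitude over `window` fixes.

    Ends shrink the window (the first and last positions average 2 fixes for
    window 3), so output length equals input length.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes to smooth")
    out = fixes.copy()
    roll = fixes[["lon", "lat"]].rolling(window, center=True, min_periods=2)
    sm = roll.mean()
    # the very first/last row of a min_periods=2 centered window is still
    # defined (2 fixes); interior rows use the full window
    out["lon_smooth"] = sm["lon"].to_numpy()
    out["lat_smooth"] = sm["lat"].to_numpy()
    return out


def label_sides(
    positions: pd.DataFrame,
    buffer: Polygon | None = None,
    lon_col: str = "lon_smooth",
    lat_col: str = "lat_smooth",
) -> np.ndarray:
    """Label each smoothed position atlantic / mediterranean / ambiguous.

    Inside the buffer polygon -> ambiguous; otherwise the side is determined
    by comparing longitude against the buffer's extent at that latitude
    (clamped to the buffer's latitude range for positions outside it, with a
    warning).
    """
    if buffer is None:
        buffer = default_buffer()
    minx, miny, maxx, maxy = buffer.bounds
    labels = np.empty(len(positions), dtype=object)
    lons = positions[lon_col].to_numpy(float)
    lats = positions[lat_col].to_numpy(float)
    warned = False
    for k, (lo, la) in enumerate(zip(lons, lats)):
        p = Point(lo, la)
        if buffer.contains(p) or buffer.touches(p):
            labels[k] = "ambiguous"
            continue
        la_c = la
        if not (miny <= la <= maxy):
            la_c = min(max(la, miny + 1e-6), maxy - 1e-6)
            if not warned:
                warnings.warn("position outside the buffer's latitude range; using nearest")
                warned = True
        cut = buffer.intersection(LineString([(minx - 360.0, la_c), (maxx + 360.0, la_c)]))
        if cut.is_empty:
            mid = (minx + maxx) / 2.0
        else:
            bx = cut.bounds
            mid = (bx[0] + bx[2]) / 2.0
        labels[k] = "atlantic" if lo < mid else "mediterranean"
    return labels


def resolve_ambiguous(labels) -> np.ndarray:
    """Replace ambiguous labels by the preceding unambiguous label.

    Leading ambiguous labels inherit the first unambiguous label (backward
    fill at the start only). Errors when every label is ambiguous.
    """
    lab = np.asarray(labels, dtype=object).copy()
    known = np.flatnonzero(lab != "ambiguous")
    if known.size == 0:
        raise ValueError("all labels ambiguous: cannot resolve sides")
    first = known[0]
    lab[:first] = lab[first]
    for i in range(first + 1, lab.size):
        if lab[i] == "ambiguous":
            lab[i] = lab[i - 1]
    return lab


def find_crossings(labels, times) -> list[tuple]:
    """(crossing_time, direction) for every label change.

    The crossing time is the midpoint of the two flanking fix timestamps —
    even across multi-day gaps, so a return that happens inside a gap is
    still dated. Direction is "departure" (mediterranean -> atlantic) or
    "return" (atlantic -> mediterranean).
    """
    lab = np.asarray(labels, dtype=object)
    t = pd.to_datetime(pd.Series(list(times))).reset_index(drop=True)
    out = []
    for i in range(1, lab.size):
        if lab[i] != lab[i - 1]:
            mid = t.iloc[i - 1] + (t.iloc[i] - t.iloc[i - 1]) / 2
            direction = "departure" if lab[i] == "atlantic" else "return"
            out.append((mid, direction))
    return out


@dataclass
class MigrationBounds:
    """The core migration of one track and its outbound/return partition."""

    departure_date: pd.Timestamp | None
    return_date: pd.Timestamp | None
    apex_index: int  # index into the fixes frame
    migration_indices: np.ndarray
    outbound_indices: np.ndarray
    return_indices: np.ndarray
    open_ended: bool = False  # track ended at sea before returning


def core_migration(labels, times) -> dict | None:
    """Select the longest Atlantic run as the core migration.

    Returns None when the track never enters the Atlantic (a track with no
    migration fixes — a value, not an error). A run that reaches the end of
    the track is open-ended (the tag stopped before return); its return date
    is None. Duration ties break to the earlier run.
    """
    lab = np.asarray(labels, dtype=object)
    t = pd.to_datetime(pd.Series(list(times))).reset_index(drop=True)
    runs = []  # (start_idx, end_idx inclusive)
    i = 0
    while i < lab.size:
        if lab[i] == "atlantic":
            j = i
            while j + 1 < lab.size and lab[j + 1] == "atlantic":
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        return None
    scored = []
    for i, j in runs:
        start = t.iloc[i - 1] + (t.iloc[i] - t.iloc[i - 1]) / 2 if i > 0 else t.iloc[i]
        end = t.iloc[j] + (t.iloc[j + 1] - t.iloc[j]) / 2 if j + 1 < lab.size else t.iloc[j]
        scored.append(((end - start), i, j, start, end))
    dur, i, j, start, end = max(scored, key=lambda s: (s[0], -s[1]))
    open_ended = j == lab.size - 1
    return {
        "indices": np.arange(i, j + 1),
        "departure_date": start if i > 0 else None,
        "return_date": None if open_ended else end,
        "open_ended": open_ended,
    }


def split_at_apex(lats) -> tuple[int, np.ndarray, np.ndarray]:
    """Apex index and (outbound, return) index partition of migration fixes.

    The apex is the fix whose latitude is closest to the 98th percentile
    (linear-interpolation percentile) of migration latitudes; earliest fix on
    ties. Fixes before the apex are outbound; the apex opens the return
    section, so return speed is measured from the apex onwards.
    """
    lats = np.asarray(lats, float)
    if lats.size < 3:
        raise ValueError("need at least 3 migration fixes to split at the apex")
    q = float(np.percentile(lats, 98))
    apex = int(np.argmin(np.abs(lats - q)))
    return apex, np.arange(0, apex), np.arange(apex, lats.size)


def segment_track(
    fixes: pd.DataFrame,
    buffer: Polygon | None = None,
    window: int = 3,
    time_col: str = "date",
) -> MigrationBounds | None:
    """Full segmentation of one filtered track.

    Smooths, labels sides, resolves ambiguity, finds buffer crossings,
    selects the core migration and splits it at the apex. Returns None when
    the track holds no migration fixes, or a bounds object with
    ``open_ended=True`` when the tag stopped before return.
    """
    fixes = fixes.reset_index(drop=True)
    sm = rolling_positions(fixes, window=window)
    labels = resolve_ambiguous(label_sides(sm, buffer))
    core = core_migration(labels, fixes[time_col])
    if core is None:
        return None
    idx = core["indices"]
    if idx.size < 3:
        return None
    lats = fixes["lat"].to_numpy(float)[idx]
    apex_rel, out_rel, ret_rel = split_at_apex(lats)
    return MigrationBounds(
        departure_date=core["departure_date"],
        return_date=core["return_date"],
        apex_index=int(idx[apex_rel]),
        migration_indices=idx,
        outbound_indices=idx[out_rel],
        return_indices=idx[ret_rel],
        open_ended=core["open_ended"],
    )
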