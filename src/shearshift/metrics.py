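"""Per-migration movement metrics.

Great-circle (beeline) distances, section travel speeds, the speed over the
initial fraction of return migration, the speed over a fixed latitudinal band,
and the shortest sea-route distance computed over a rasterized ocean grid that
never crosses land.

All distances use a spherical Earth of radius ``EARTH_RADIUS_KM``; all speeds
are km/h over elapsed clock time (timestamps are UTC by contract).
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.prepared import prep

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "path_length_km",
    "section_speed_kmh",
    "initial_return_speed",
    "band_speed",
    "LandMask",
    "OceanGrid",
    "route_distance_km",
    "summarize_migration",
]


def haversine_km(p1, p2):
    """Great-circle distance in km between (lon, lat) points, elementwise.

    Accepts scalars or arrays; coordinates in decimal degrees.
    """
    lon1, lat1 = np.radians(np.asarray(p1[0], float)), np.radians(np.asarray(p1[1], float))
    lon2, lat2 = np.radians(np.asarray(p2[0], float)), np.radians(np.asarray(p2[1], float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(d) if np.ndim(d) == 0 else d


def path_length_km(lons, lats) -> float:
    """Summed consecutive great-circle distance along a polyline, km."""
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    if lons.size < 2:
        return 0.0
    seg = haversine_km((lons[:-1], lats[:-1]), (lons[1:], lats[1:]))
    return float(np.sum(seg))


def _elapsed_hours(times) -> float:
    t = pd.to_datetime(pd.Series(list(times)), utc=True)
    return float((t.iloc[-1] - t.iloc[0]).total_seconds() / 3600.0)


def section_speed_kmh(times, lons, lats) -> float:
    """Average travel speed over one track section.

    Sum of consecutive great-circle distances divided by total elapsed hours.
    Returns NaN (flagged undefined) for fewer than 2 fixes or zero elapsed time.
    """
    lons = np.asarray(lons, float)
    if lons.size < 2:
        return float("nan")
    hours = _elapsed_hours(times)
    if hours <= 0:
        return float("nan")
    return path_length_km(lons, lats) / hours


def initial_return_speed(times, lons, lats, fraction: float = 0.25) -> float:
    """Speed over the first `fraction` of the return migration, by elapsed time.

    Fixes whose timestamps fall within the first ``fraction`` of the
    apex-to-return interval are used; the window is time-based so the estimate
    is robust to irregular fix dropout. NaN if fewer than 2 such fixes.
    """
    t = pd.to_datetime(pd.Series(list(times)), utc=True).to_numpy()
    if t.size < 2:
        return float("nan")
    cutoff = t[0] + (t[-1] - t[0]) * fraction
    sel = t <= cutoff
    if sel.sum() < 2:
        return float("nan")
    return section_speed_kmh(t[sel], np.asarray(lons, float)[sel], np.asarray(lats, float)[sel])


def band_speed(times, lons, lats, south: float = 35.0, north: float = 45.0) -> float:
    """Speed over the maximal contiguous run of fixes with latitude in [south, north].

    Used to compare speeds over a fixed band every bird must traverse,
    removing the habitat confound of differing destinations. NaN if fewer
    than 2 in-band fixes in the longest run.
    """
    lats = np.asarray(lats, float)
    inband = (lats >= south) & (lats <= north)
    if not inband.any():
        return float("nan")
    # maximal contiguous True run (longest by count, earliest on ties)
    best = (0, 0)
    i = 0
    n = lats.size
    while i < n:
        if inband[i]:
            j = i
            while j + 1 < n and inband[j + 1]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j + 1
        else:
            i += 1
    i, j = best
    if j - i < 1:
        return float("nan")
    sl = slice(i, j + 1)
    t = pd.to_datetime(pd.Series(list(times)), utc=True).to_numpy()
    return section_speed_kmh(t[sl], np.asarray(lons, float)[sl], lats[sl])


# ---------------------------------------------------------------------------
# Land mask and sea-route distance
# ---------------------------------------------------------------------------

# 16-connectivity: the 8 king moves plus 8 knight moves; knight moves cut the
# metric distortion of the grid metric from ~8% to ~2.8%.
_KING = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_KNIGHT = [(-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1)]


@dataclass
class LandMask:
    """Land polygons (WGS84 lon/lat) used to constrain sea routes.

    `geometry` is any shapely geometry whose interior is land; everything
    else inside the working bounding box is ocean.
    """

    geometry: BaseGeometry
    bbox: tuple = (-22.0, 42.0, 30.0, 60.0)  # west, east, south, north

    @classmethod
    def from_geojson(cls, path, bbox=(-22.0, 42.0, 30.0, 60.0)) -> "LandMask":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geoms = [shape(f["geometry"]) for f in gj["features"]]
        elif gj.get("type") == "Feature":
            geoms = [shape(gj["geometry"])]
        else:
            geoms = [shape(gj)]
        return cls(geometry=unary_union(geoms), bbox=bbox)

    def to_geojson(self, path) -> None:
        gj = {
            "type": "Feature",
            "properties": {"role": "land"},
            "geometry": mapping(self.geometry),
        }
        with open(path, "w") as fh:
            json.dump(gj, fh)

    def rasterize(self, resolution_deg: float = 0.25) -> "OceanGrid":
        return OceanGrid.build(self, resolution_deg)


@dataclass
class OceanGrid:
    """Rasterized ocean/land grid over a land mask's bounding box.

    A cell is ocean when its center is not inside any land polygon. Nodes are
    ocean cell centers; edges are 16-neighbour moves weighted by haversine
    length, with knight moves blocked when they would clip a land cell.
    """

    ocean: np.ndarray  # (nlat, nlon) bool
    lats: np.ndarray  # cell-center latitudes
    lons: np.ndarray  # cell-center longitudes
    resolution_deg: float
    _prepared: object = field(default=None, repr=False, compare=False)

    @classmethod
    def build(cls, mask: LandMask, resolution_deg: float = 0.25) -> "OceanGrid":
        west, east, south, north = mask.bbox
        lons = np.arange(west + resolution_deg / 2, east, resolution_deg)
        lats = np.arange(south + resolution_deg / 2, north, resolution_deg)
        prepared = prep(mask.geometry)
        from shapely.geometry import Point

        ocean = np.ones((lats.size, lons.size), dtype=bool)
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                if prepared.contains(Point(lo, la)):
                    ocean[i, j] = False
        return cls(ocean=ocean, lats=lats, lons=lons, resolution_deg=resolution_deg)

    # -- node helpers ------------------------------------------------------
    def cell_of(self, lon: float, lat: float) -> tuple:
        i = int(np.clip(np.searchsorted(self.lats, lat) - 1, 0, self.lats.size - 1))
        if i + 1 < self.lats.size and abs(self.lats[i + 1] - lat) < abs(self.lats[i] - lat):
            i += 1
        j = int(np.clip(np.searchsorted(self.lons, lon) - 1, 0, self.lons.size - 1))
        if j + 1 < self.lons.size and abs(self.lons[j + 1] - lon) < abs(self.lons[j] - lon):
            j += 1
        return i, j

    def center(self, node: tuple) -> tuple:
        return float(self.lons[node[1]]), float(self.lats[node[0]])

    def snap_to_ocean(self, lon: float, lat: float, max_cells: int = 2) -> tuple:
        """Nearest ocean cell within `max_cells` Chebyshev distance, else error."""
        i0, j0 = self.cell_of(lon, lat)
        if self.ocean[i0, j0]:
            return i0, j0
        best = None
        for r in range(1, max_cells + 1):
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if max(abs(di), abs(dj)) != r:
                        continue
                    i, j = i0 + di, j0 + dj
                    if 0 <= i < self.lats.size and 0 <= j < self.lons.size and self.ocean[i, j]:
                        d = haversine_km((lon, lat), self.center((i, j)))
                        if best is None or d < best[0]:
                            best = (d, (i, j))
            if best is not None:
                return best[1]
        raise ValueError(
            f"point ({lon:.3f}, {lat:.3f}) is not within {max_cells} cells of ocean"
        )

    def neighbours(self, node: tuple, connectivity: int = 16):
        i, j = node
        moves = _KING if connectivity == 8 else _KING + _KNIGHT
        for di, dj in moves:
            ni, nj = i + di, j + dj
            if not (0 <= ni < self.lats.size and 0 <= nj < self.lons.size):
                continue
            if not self.ocean[ni, nj]:
                continue
            if abs(di) + abs(dj) == 3:
                # knight move: the two cells flanking the jump must be ocean
                # so the route cannot corner-cut across land
                if abs(di) == 2:
                    flank = [(i + di // 2, j), (i + di // 2, j + dj)]
                else:
                    flank = [(i, j + dj // 2), (i + di, j + dj // 2)]
                if not all(self.ocean[fi, fj] for fi, fj in flank):
                    continue
            yield (ni, nj), haversine_km(self.center(node), self.center((ni, nj)))

    def to_networkx(self, connectivity: int = 16):
        """Ocean graph as a networkx.Graph (used for oracle comparisons)."""
        import networkx as nx

        g = nx.Graph()
        for i in range(self.lats.size):
            for j in range(self.lons.size):
                if not self.ocean[i, j]:
                    continue
                for nb, w in self.neighbours((i, j), connectivity):
                    g.add_edge((i, j), nb, weight=w)
        return g


def _astar(grid: OceanGrid, start: tuple, goal: tuple, connectivity: int = 16):
    """Label-setting shortest path (A*) with the great-circle heuristic.

    The great-circle distance to the goal never exceeds the over-water path
    length, so the heuristic is admissible and the first settled goal label
    is optimal.
    """
    goal_ll = grid.center(goal)
    h0 = haversine_km(grid.center(start), goal_ll)
    frontier = [(h0, 0.0, start)]
    dist = {start: 0.0}
    parent = {start: None}
    settled = set()
    while frontier:
        f, g, node = heapq.heappop(frontier)
        if node in settled:
            continue
        settled.add(node)
        if node == goal:
            path = []
            while node is not None:
                path.append(node)
                node = parent[node]
            return g, path[::-1]
        for nb, w in grid.neighbours(node, connectivity):
            nd = g + w
            if nd < dist.get(nb, np.inf):
                dist[nb] = nd
                parent[nb] = node
                heapq.heappush(frontier, (nd + haversine_km(grid.center(nb), goal_ll), nd, nb))
    raise ValueError(
        f"no sea route between {grid.center(start)} and {grid.center(goal)}: "
        "endpoints lie in disconnected ocean components"
    )


def route_distance_km(
    origin,
    dest,
    mask: LandMask,
    resolution_deg: float = 0.25,
    connectivity: int = 16,
    grid: OceanGrid | None = None,
):
    """Shortest over-water route length (km) and its polyline.

    origin/dest are (lon, lat); each is snapped to the nearest ocean cell
    within 2 cells. Returns (length_km, [(lon, lat), ...]).
    """
    if grid is None:
        grid = mask.rasterize(resolution_deg)
    a = grid.snap_to_ocean(*origin)
    b = grid.snap_to_ocean(*dest)
    km, nodes = _astar(grid, a, b, connectivity)
    return km, [grid.center(n) for n in nodes]


# ---------------------------------------------------------------------------
# Per-migration summary
# ---------------------------------------------------------------------------


def summarize_migration(
    fixes: pd.DataFrame,
    bounds,
    colony_lonlat,
    mask: LandMask | None = None,
    grid: OceanGrid | None = None,
    resolution_deg: float = 0.25,
    meta: dict | None = None,
) -> dict:
    """One MigrationSummary row for a segmented migration.

    `fixes` must have timestamp/lon/lat columns; `bounds` a MigrationBounds
    from the segment stage (indices into `fixes`). Route distance is from the
    apex fix back to the colony over the ocean grid; beeline is the haversine
    between the same points.
    """
    mig = fixes.iloc[bounds.migration_indices]
    out = fixes.iloc[bounds.outbound_indices]
    ret = fixes.iloc[bounds.return_indices]
    apex = fixes.iloc[bounds.apex_index]
    t = "timestamp"
    row = dict(meta or {})
    row.update(
        median_lat=float(mig["lat"].median()),
        median_lon=float(mig["lon"].median()),
        max_lat=float(apex["lat"]),
        outbound_speed=section_speed_kmh(out[t], out["lon"], out["lat"]),
        return_speed=section_speed_kmh(ret[t], ret["lon"], ret["lat"]),
        initial_return_speed=initial_return_speed(ret[t], ret["lon"], ret["lat"]),
        band_speed_35_45=band_speed(ret[t], ret["lon"], ret["lat"]),
        beeline_km=haversine_km((float(apex["lon"]), float(apex["lat"])), colony_lonlat),
        departure_doy=float(pd.Timestamp(bounds.departure_date).dayofyear),
        return_doy=float(pd.Timestamp(bounds.return_date).dayofyear)
        if bounds.return_date is not None
        else float("nan"),
    )
    if mask is not None or grid is not None:
        try:
            km, _ = route_distance_km(
                (float(apex["lon"]), float(apex["lat"])),
                colony_lonlat,
                mask,
                resolution_deg=resolution_deg,
                grid=grid,
            )
        except ValueError as exc:
            warnings.warn(f"route distance unavailable: {exc}")
            km = float("nan")
        row["route_km"] = km
    else:
        row["route_km"] = float("nan")
    return row
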