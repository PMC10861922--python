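"""Synthetic populations of repeatedly tracked migrating shearwaters.

The generator emulates the study design that the downstream statistics need:
long-lived individuals tracked in one or more consecutive years; a bimodal
latitudinal destination distribution (a southern area off Iberia and a
northern area in Biscay); individual mean destinations plus within-individual
year-to-year responses to a warming sea-surface-temperature covariate;
outbound and return migration legs with return speed coupled to route length;
heavy-tailed, latitude-dominant geolocation noise; and (optionally) raw light
curves from a solar forward model, plus a toy coastline for sea-route tests.

Two levels are exposed. ``simulate_summaries`` draws the statistical core
directly (one row per individual-year with the true migration summaries) and
is what parameter-recovery studies use. ``simulate_population`` additionally
lays each migration out as a daily track along a coast-hugging waypoint path,
so the geolocation, segmentation and metrics stages can be exercised
end-to-end against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .metrics import LandMask, haversine_km, path_length_km

__all__ = [
    "Colony",
    "PopulationConfig",
    "simulate_summaries",
    "simulate_population",
    "simulate_track",
    "simulate_light_series",
    "simulate_sst_grid",
    "make_toy_coastline",
]


@dataclass(frozen=True)
class Colony:
    name: str
    island: str
    lon: float
    lat: float


# the four study colonies (degrees-minutes converted to decimal)
DEFAULT_COLONIES = (
    Colony("Sa Cella", "Mallorca", 2.35, 39.60),
    Colony("Sa Dragonera", "Mallorca", 2.3167, 39.5833),
    Colony("Es Bosc", "Ibiza", 1.2167, 38.9667),
    Colony("Sa Conillera", "Ibiza", 1.2167, 38.9833),
)


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth parameters of a simulated population.

    Latitude slopes are in degrees latitude per degC of the SST covariate
    (between: response of individual mean destinations to individual mean
    SST; within: response of yearly deviations). Speed slopes are km/h per
    degree of maximum latitude, phenology slopes days per degree, matching
    the structure of the fitted models downstream.
    """

    n_individuals: int = 60
    year_start: int = 2010
    year_end: int = 2018
    colonies: tuple = DEFAULT_COLONIES
    # SST covariate: one scalar per year (box-mean proxy)
    sst_base: float = 18.0
    sst_trend: float = 0.15  # degC / year
    sst_noise_sd: float = 0.3
    # destination-latitude model
    between_slope: float = 1.421
    within_slope: float = 0.662
    individual_sd: float = 1.0
    residual_sd: float = 0.7
    area_means: tuple = (38.5, 47.5)  # southern, northern (degN)
    p_north_base: float = 0.35  # P(north) at the base SST
    p_north_logit_slope: float = 1.79  # log-odds per degC
    # apex latitude sits slightly poleward of the median latitude
    apex_offset_mean: float = 1.0
    apex_offset_sd: float = 0.3
    # speeds
    outbound_speed_mean: float = 4.0  # km/h, daily average
    outbound_speed_sd: float = 0.8  # between individuals
    outbound_speed_year_sd: float = 0.3  # year-to-year within an individual
    return_speed_base: float = 3.0  # km/h at the reference latitude
    speed_between_slope: float = 0.227  # km/h per deg max latitude
    speed_within_slope: float = 0.207
    speed_outbound_coupling: float = 0.15
    speed_area_effect: float = 0.3  # northern-area additive term
    speed_residual_sd: float = 0.4
    return_speed_intercept: float = 2.2  # km/h, track path model
    return_speed_per_100km: float = 0.0713  # km/h per 100 km route length
    # phenology (day of year)
    departure_doy_mean: float = 150.0
    departure_doy_sd: float = 12.0
    departure_south_effect: float = 11.4  # southern birds leave later
    return_doy_base: float = 290.0
    return_south_effect: float = 38.5
    return_mallorca_effect: float = -9.8
    return_between_slope: float = 5.4  # d per deg max latitude
    return_within_slope: float = 4.4
    return_residual_sd: float = 8.0
    # repeated-tracking structure: geometric retention, mean tracks/individual
    mean_tracks_per_individual: float = 2.0
    # geolocation-like observation noise (latitude-dominant)
    fix_noise_lat_sd: float = 1.0
    fix_noise_lon_sd: float = 0.5
    fix_dropout_p: float = 0.05
    seed: int = 0

    def __post_init__(self):
        sds = (
            self.sst_noise_sd, self.individual_sd, self.residual_sd,
            self.outbound_speed_sd, self.speed_residual_sd,
            self.departure_doy_sd, self.return_residual_sd,
            self.fix_noise_lat_sd, self.fix_noise_lon_sd, self.apex_offset_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all standard deviations must be >= 0")
        if not (0 <= self.fix_dropout_p < 1):
            raise ValueError("fix_dropout_p must be in [0, 1)")
        if self.area_means[0] >= self.area_means[1]:
            raise ValueError("southern area mean must lie south of the northern mean")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    # reference values used to center the generative linear predictors
    @property
    def sst_ref(self) -> float:
        return self.sst_base + self.sst_trend * (len(self.years) - 1) / 2.0

    @property
    def lat_ref(self) -> float:
        return float(np.mean(self.area_means))


def _logit(p):
    return np.log(p / (1.0 - p))


def _draw_sst(config: PopulationConfig, rng: np.random.Generator) -> pd.Series:
    years = config.years
    sst = (
        config.sst_base
        + config.sst_trend * (years - config.year_start)
        + rng.normal(0.0, config.sst_noise_sd, size=years.size)
    )
    return pd.Series(sst, index=years)


def simulate_summaries(
    config: PopulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw the statistical core: one row of true summaries per individual-year.

    Columns: individual_id, island, colony, sex, year, sst, area,
    median_lat, max_lat, outbound_speed, return_speed, departure_doy,
    return_doy. Deterministic given (config, seed).
    """
    if config.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if config.year_end <= config.year_start:
        raise ValueError("need more than one study year for within-individual contrasts")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sst_by_year = _draw_sst(config, rng)
    years = config.years

    rows = []
    for i in range(config.n_individuals):
        ind = f"ind{i:04d}"
        colony = config.colonies[rng.integers(len(config.colonies))]
        sex = "M" if rng.random() < 0.5 else "F"
        first = int(rng.integers(years[0], years[-1] + 1))
        n_tracks = int(
            min(rng.geometric(1.0 / config.mean_tracks_per_individual), years[-1] - first + 1)
        )
        tracked = np.arange(first, first + n_tracks)
        sst = sst_by_year.loc[tracked].to_numpy()
        mean_sst = float(np.mean(sst))
        dev_sst = sst - mean_sst

        p_north = 1.0 / (
            1.0
            + np.exp(
                -(
                    _logit(config.p_north_base)
                    + config.p_north_logit_slope * (mean_sst - config.sst_ref)
                )
            )
        )
        area = "north" if rng.random() < p_north else "south"
        area_mean = config.area_means[1 if area == "north" else 0]
        u = rng.normal(0.0, config.individual_sd)
        outbound_i = rng.normal(config.outbound_speed_mean, config.outbound_speed_sd)
        outbound_it = np.maximum(
            outbound_i + rng.normal(0.0, config.outbound_speed_year_sd, size=tracked.size),
            0.5,
        )

        med_lat = (
            area_mean
            + u
            + config.between_slope * (mean_sst - config.sst_ref)
            + config.within_slope * dev_sst
            + rng.normal(0.0, config.residual_sd, size=tracked.size)
        )
        max_lat = med_lat + rng.normal(
            config.apex_offset_mean, config.apex_offset_sd, size=tracked.size
        )
        mean_maxlat = float(np.mean(max_lat))
        dev_maxlat = max_lat - mean_maxlat

        return_speed = (
            config.return_speed_base
            + config.speed_between_slope * (mean_maxlat - config.lat_ref)
            + config.speed_within_slope * dev_maxlat
            + config.speed_outbound_coupling * (outbound_it - config.outbound_speed_mean)
            + config.speed_area_effect * (area == "north")
            + rng.normal(0.0, config.speed_residual_sd, size=tracked.size)
        )
        return_speed = np.maximum(return_speed, 0.5)

        departure_doy = (
            config.departure_doy_mean
            + config.departure_south_effect * (area == "south")
            + rng.normal(0.0, config.departure_doy_sd, size=tracked.size)
        )
        return_doy = (
            config.return_doy_base
            + config.return_south_effect * (area == "south")
            + config.return_mallorca_effect * (colony.island == "Mallorca")
            + config.return_between_slope * (mean_maxlat - config.lat_ref)
            + config.return_within_slope * dev_maxlat
            + rng.normal(0.0, config.return_residual_sd, size=tracked.size)
        )
        return_doy = np.maximum(return_doy, departure_doy + 45.0)

        for k, year in enumerate(tracked):
            rows.append(
                dict(
                    individual_id=ind,
                    island=colony.island,
                    colony=colony.name,
                    sex=sex,
                    year=int(year),
                    sst=float(sst[k]),
                    area=area,
                    median_lat=float(med_lat[k]),
                    max_lat=float(max_lat[k]),
                    outbound_speed=float(outbound_it[k]),
                    return_speed=float(return_speed[k]),
                    departure_doy=float(departure_doy[k]),
                    return_doy=float(return_doy[k]),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy coastline
# ---------------------------------------------------------------------------


def make_toy_coastline() -> LandMask:
    """Toy land polygons enclosing a connected ocean for route-distance tests.

    An "Iberia" block (10W-0E, 36-44N), a "Europe" block north of the
    Mediterranean joined to Iberia across the Pyrenees, a "Brittany"
    promontory, and an "Africa" block leaving a narrow Strait-of-Gibraltar
    channel at ~35.4-36N. The Mediterranean only communicates with the
    Atlantic through that channel, so colony-to-Biscay routes must round
    Iberia, diverging strongly from the beeline.
    """
    # edges avoid half- and quarter-degree grid lines so cell centers never
    # sit exactly on a polygon boundary at common rasterization resolutions
    iberia = box(-10.1, 35.9, 0.1, 44.1)
    europe = box(-0.6, 43.4, 42.0, 60.0)
    brittany = box(-4.6, 47.9, -0.6, 49.6)
    africa = box(-5.3, 30.0, 42.0, 35.4)
    # union (not MultiPolygon): Iberia and Europe deliberately overlap at the
    # Pyrenees so the Mediterranean is sealed there
    return LandMask(geometry=unary_union([iberia, europe, brittany, africa]))


# ---------------------------------------------------------------------------
# Track forward model
# ---------------------------------------------------------------------------

_GIBRALTAR = (-5.6, 35.7)
_SW_CORNER = (-11.0, 36.5)
_NW_CORNER = (-11.0, 43.5)
_BISCAY_TURN = (-8.5, 45.2)
_NORTH_DEST_LON = -5.5
_SOUTH_DEST_LON = -11.0


def _waypoints(colony: Colony, area: str, dest_lat: float, coast: LandMask) -> list:
    """Coast-hugging piecewise great-circle waypoint path colony -> destination."""
    if area == "south":
        dest = (_SOUTH_DEST_LON, dest_lat)
        pts = [(colony.lon, colony.lat), _GIBRALTAR, _SW_CORNER, (_SW_CORNER[0], dest_lat), dest]
    else:
        dest = (_NORTH_DEST_LON, dest_lat)
        pts = [
            (colony.lon, colony.lat),
            _GIBRALTAR,
            _SW_CORNER,
            _NW_CORNER,
            _BISCAY_TURN,
            dest,
        ]
    # destination on land (extreme latitude draws): push west to open sea
    while coast.geometry.contains(Point(*pts[-1])):
        warnings.warn(f"destination {pts[-1]} on land; repositioning west to the sea")
        pts[-1] = (pts[-1][0] - 0.5, pts[-1][1])
    return pts


def _interp_along(pts: list, s_km: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions at arc distances s_km along a piecewise path (linear in lon/lat)."""
    pts = np.asarray(pts, float)
    seg = np.array(
        [haversine_km(tuple(pts[k]), tuple(pts[k + 1])) for k in range(len(pts) - 1)]
    )
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.clip(s_km, 0.0, cum[-1])
    lons = np.interp(s, cum, pts[:, 0])
    lats = np.interp(s, cum, pts[:, 1])
    return lons, lats


def simulate_track(
    truth: pd.Series | dict,
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
    coast: LandMask | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Daily positions for one individual-year migration.

    Colony residence, outbound leg (colony -> Gibraltar -> coastal path ->
    destination) at the true outbound speed, residence with small jitter,
    return along the same path at the true return speed, then colony again.
    The truth departure/return dates are the dates the bird passes the
    Gibraltar waypoint out and back. With ``noise``, independent Gaussian
    perturbations (latitude sd > longitude sd) and day dropout are applied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if coast is None:
        coast = make_toy_coastline()
    t = truth if isinstance(truth, dict) else truth.to_dict()
    colony = next(c for c in config.colonies if c.name == t["colony"])
    pts = _waypoints(colony, t["area"], t["median_lat"], coast)
    d_gib = haversine_km((colony.lon, colony.lat), _GIBRALTAR)
    total = path_length_km(*zip(*[(p[0], p[1]) for p in pts]))
    v_out = t["outbound_speed"] * 24.0  # km/day
    v_ret = t["return_speed"] * 24.0

    year = int(t["year"])
    day0 = pd.Timestamp(year=year, month=1, day=1, hour=12, tz="UTC")
    depart = day0 + pd.Timedelta(days=t["departure_doy"] - 1)
    leave_colony = depart - pd.Timedelta(days=d_gib / v_out)
    arrive = leave_colony + pd.Timedelta(days=total / v_out)
    ret_date = day0 + pd.Timedelta(days=t["return_doy"] - 1)
    leave_dest = ret_date - pd.Timedelta(days=(total - d_gib) / v_ret)
    if leave_dest < arrive + pd.Timedelta(days=5):
        leave_dest = arrive + pd.Timedelta(days=5)
        ret_date = leave_dest + pd.Timedelta(days=(total - d_gib) / v_ret)
    home = leave_dest + pd.Timedelta(days=total / v_ret)

    start = leave_colony - pd.Timedelta(days=30)
    end = home + pd.Timedelta(days=20)
    times = pd.date_range(start.floor("D") + pd.Timedelta(hours=12), end, freq="D")

    lons = np.empty(times.size)
    lats = np.empty(times.size)
    for k, tt in enumerate(times):
        if tt <= leave_colony or tt > home:
            lons[k], lats[k] = colony.lon, colony.lat
        elif tt <= arrive:
            s = (tt - leave_colony) / pd.Timedelta(days=1) * v_out
            lo, la = _interp_along(pts, np.array([s]))
            lons[k], lats[k] = lo[0], la[0]
        elif tt <= leave_dest:
            lons[k], lats[k] = pts[-1]
        else:
            s = (tt - leave_dest) / pd.Timedelta(days=1) * v_ret
            lo, la = _interp_along(pts[::-1], np.array([s]))
            lons[k], lats[k] = lo[0], la[0]

    # ground-truth buffer-crossing dates from the noise-free path: when the
    # true track leaves the transition corridor on the Atlantic side and when
    # it re-enters Mediterranean waters proper
    from .segment import core_migration, default_buffer, label_sides, resolve_ambiguous

    true_df = pd.DataFrame({"lon_smooth": lons, "lat_smooth": lats})
    true_labels = resolve_ambiguous(label_sides(true_df, default_buffer()))
    true_core = core_migration(true_labels, times)
    buffer_departure = true_core["departure_date"] if true_core else None
    buffer_return = true_core["return_date"] if true_core else None

    df = pd.DataFrame(
        {
            "individual_id": t["individual_id"],
            "island": t["island"],
            "sex": t["sex"],
            "deploy_year": year,
            "timestamp": times,
            "lon_true": lons,
            "lat_true": lats,
        }
    )
    # small residence jitter so the bird is not perfectly stationary
    resident = (times > arrive) & (times <= leave_dest)
    df.loc[resident, "lon_true"] += rng.normal(0.0, 0.15, resident.sum())
    df.loc[resident, "lat_true"] += rng.normal(0.0, 0.15, resident.sum())
    if noise:
        df["lon"] = df["lon_true"] + rng.normal(0.0, config.fix_noise_lon_sd, len(df))
        df["lat"] = df["lat_true"] + rng.normal(0.0, config.fix_noise_lat_sd, len(df))
        keep = rng.random(len(df)) >= config.fix_dropout_p
        df = df[keep].reset_index(drop=True)
    else:
        df["lon"] = df["lon_true"]
        df["lat"] = df["lat_true"]
    df.attrs["truth"] = dict(
        t,
        departure_date=str(depart.date()),
        return_date=str(ret_date.date()),
        buffer_departure=buffer_departure,
        buffer_return=buffer_return,
        route_km=float(total - d_gib),
    )
    return df


def simulate_population(
    config: PopulationConfig, seed: int | None = None
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate the whole study: daily tracks plus the truth table.

    Returns (tracks, truth) where `tracks` holds one DataFrame per
    individual-year (daily fixes with and without observation noise) and
    `truth` one row per simulated migration with the generative values.
    Deterministic given (config, seed).
    """
    truth = simulate_summaries(config, seed)
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    coast = make_toy_coastline()
    tracks = []
    dep_dates, ret_dates, routes = [], [], []
    for _, row in truth.iterrows():
        tr = simulate_track(row, config, rng=rng, coast=coast)
        tracks.append(tr)
        dep_dates.append(tr.attrs["truth"]["departure_date"])
        ret_dates.append(tr.attrs["truth"]["return_date"])
        routes.append(tr.attrs["truth"]["route_km"])
    truth = truth.assign(departure_date=dep_dates, return_date=ret_dates, route_km=routes)
    return tracks, truth


# ---------------------------------------------------------------------------
# Light forward model
# ---------------------------------------------------------------------------

_LUX_AT_THRESHOLD = 10.0
_LUX_SLOPE = 0.8  # per degree of solar elevation
_LUX_CEIL = 1.0e4


def simulate_light_series(
    track: pd.DataFrame, sampling_minutes: float = 2.0, elevation_deg: float = -4.5
) -> pd.DataFrame:
    """Raw illuminance sampled from a solar forward model along a track.

    Illuminance is a smooth monotone function of solar elevation that crosses
    10 lx exactly when the sun is at `elevation_deg` at the day's true
    position: lux = 10 * exp(0.8 * (elevation - elevation_deg)), capped at
    1e4 lx. Days with no threshold crossing (polar day/night) simply emit a
    curve that never crosses 10 lx.
    """
    from .geolocate import solar_position

    rows = []
    for _, day in track.iterrows():
        t0 = pd.Timestamp(day["timestamp"]).floor("D")
        times = pd.date_range(t0, t0 + pd.Timedelta(days=1), freq=f"{sampling_minutes}min")[:-1]
        el = solar_position(times, day["lon_true"], day["lat_true"])
        lux = np.minimum(_LUX_AT_THRESHOLD * np.exp(_LUX_SLOPE * (el - elevation_deg)), _LUX_CEIL)
        rows.append(pd.DataFrame({"timestamp": times, "lux": lux}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# SST emitters
# ---------------------------------------------------------------------------


def simulate_sst_grid(
    config: PopulationConfig,
    seed: int | None = None,
    box_lonlat: tuple = (-12.0, -1.0, 38.0, 51.0),
    resolution_deg: float = 0.5,
    lat_gradient: float = -0.3,
):
    """Gridded monthly SST (xarray Dataset) consistent with the scalar proxy.

    The July/August field for each year equals the year's scalar SST plus a
    linear latitude gradient centered on the box, so the unweighted box mean
    recovers the scalar exactly. Intended for I/O and proxy-extraction tests.
    """
    import xarray as xr

    rng = np.random.default_rng(config.seed if seed is None else seed)
    sst_by_year = _draw_sst(config, rng)
    west, east, south, north = box_lonlat
    lons = np.arange(west + resolution_deg / 2, east, resolution_deg)
    lats = np.arange(south + resolution_deg / 2, north, resolution_deg)
    mid = (lats[0] + lats[-1]) / 2.0
    times, cubes = [], []
    for year, val in sst_by_year.items():
        for month in (7, 8):
            times.append(pd.Timestamp(int(year), month, 15))
            field = val + lat_gradient * (lats[:, None] - mid) + np.zeros((1, lons.size))
            cubes.append(field)
    data = np.stack(cubes)
    return xr.Dataset(
        {"sst": (("time", "lat", "lon"), data)},
        coords={"time": pd.DatetimeIndex(times), "lat": lats, "lon": lons},
    )


def sst_table(config: PopulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-year scalar SST table (year, sst_c) matching simulate_summaries."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s = _draw_sst(config, rng)
    return pd.DataFrame({"year": s.index.to_numpy(int), "sst_c": s.to_numpy()})
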