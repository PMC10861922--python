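"""End-to-end orchestration: simulate -> (geolocate) -> segment -> metrics -> infer.

A single RunConfig drives every stage with reproducible seeds. In paper mode
the printed analysis constants (10 lx threshold, -4.5 deg elevation, 55 km/h
speed filter, study bounding box, 100-fix minimum, 3-fix rolling window, 25%
initial-return fraction, 35-45N band, SST box and months, year batches) are
locked and cannot be overridden. Every run writes its resolved configuration
and seed alongside the outputs, and the run report reconciles track counts:
input = retained + rejected-by-QC + no-migration + open-ended.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geolocate, infer, metrics, segment, synthetic

__all__ = ["RunConfig", "run", "PAPER_LOCKED"]

# printed analysis constants, locked in paper mode
PAPER_LOCKED = dict(
    threshold_lux=10.0,
    elevation_deg=-4.5,
    max_speed_kmh=55.0,
    bbox=(-22.0, 42.0, 30.0, 60.0),
    min_fixes=100,
    rolling_window=3,
    initial_fraction=0.25,
    band=(35.0, 45.0),
    sst_box=(-12.0, -1.0, 38.0, 51.0),
    sst_months=(7, 8),
    batches=((2010, 2012), (2013, 2015), (2016, 2018)),
)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    paper_mode: bool = True
    # synthetic stage
    simulate: bool = True
    n_individuals: int = 60
    simulate_overrides: dict = field(default_factory=dict)
    use_light: bool = False  # run the light->fix stage instead of direct positions
    light_sampling_minutes: float = 2.0
    # direct inputs (bypass simulation)
    fixes_csv: str | None = None
    sst_csv: str | None = None
    buffer_geojson: str | None = None
    mask_geojson: str | None = None
    # stage parameters (locked in paper mode)
    threshold_lux: float = 10.0
    elevation_deg: float = -4.5
    equinox_window_days: float = 15.0
    max_speed_kmh: float = 55.0
    bbox: tuple = (-22.0, 42.0, 30.0, 60.0)
    min_fixes: int = 100
    rolling_window: int = 3
    initial_fraction: float = 0.25
    band: tuple = (35.0, 45.0)
    resolution_deg: float = 0.25
    sst_box: tuple = (-12.0, -1.0, 38.0, 51.0)
    sst_months: tuple = (7, 8)
    batches: tuple = ((2010, 2012), (2013, 2015), (2016, 2018))
    n_boot: int = 1000

    def __post_init__(self):
        if self.paper_mode:
            for key, locked in PAPER_LOCKED.items():
                got = getattr(self, key)
                if tuple(np.ravel(got)) != tuple(np.ravel(locked)):
                    raise ValueError(
                        f"paper_mode locks {key} to {locked}; got {got}. "
                        "Set paper_mode: false to override."
                    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("bbox", "band", "sst_box", "sst_months"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "batches" in raw and raw["batches"] is not None:
            raw["batches"] = tuple(tuple(b) for b in raw["batches"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# shearshift config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run summary dict.

    Writes per-stage CSVs (with a config-hash header comment), the resolved
    config, and report.txt into `config.out_dir`. A failing stage aborts
    with the stage named; outputs of earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh)
    report: list[str] = [f"shearshift run (config {cfg_hash}, seed {config.seed})"]
    timing: dict = {}
    stage = "setup"
    try:
        # ------------------------------------------------------------ simulate
        stage = "simulate"
        t0 = time.perf_counter()
        buffer = (
            segment.load_buffer(config.buffer_geojson)
            if config.buffer_geojson
            else segment.default_buffer()
        )
        if config.simulate:
            sim_cfg = synthetic.PopulationConfig(
                n_individuals=config.n_individuals,
                seed=config.seed,
                **config.simulate_overrides,
            )
            tracks, truth = synthetic.simulate_population(sim_cfg, seed=config.seed)
            sst = synthetic.sst_table(sim_cfg, seed=config.seed)
            coast = synthetic.make_toy_coastline()
            _write_csv(pd.concat(tracks, ignore_index=True), out / "tracks.csv", cfg_hash)
            _write_csv(truth, out / "truth.csv", cfg_hash)
            _write_csv(sst, out / "sst.csv", cfg_hash)
            coast.to_geojson(out / "land_mask.geojson")
        else:
            if config.fixes_csv is None:
                raise ValueError("simulate disabled and no fixes_csv supplied")
            raw = pd.read_csv(config.fixes_csv, comment="#", parse_dates=["timestamp"])
            tracks = [g for _, g in raw.groupby(["individual_id", "deploy_year"], sort=True)]
            truth = None
            sst = (
                pd.read_csv(config.sst_csv, comment="#") if config.sst_csv else None
            )
            coast = (
                metrics.LandMask.from_geojson(config.mask_geojson)
                if config.mask_geojson
                else synthetic.make_toy_coastline()
            )
        timing["simulate"] = time.perf_counter() - t0
        report.append(f"input tracks: {len(tracks)}")

        # ------------------------------------------- geolocate (optional light)
        stage = "geolocate"
        t0 = time.perf_counter()
        if config.use_light:
            relocated = []
            for tr in tracks:
                light = synthetic.simulate_light_series(
                    tr, config.light_sampling_minutes, config.elevation_deg
                )
                fx = geolocate.fixes_from_light(
                    light, config.threshold_lux, config.elevation_deg
                )
                fx["timestamp"] = fx["date"] + pd.Timedelta(hours=12)
                for col in ("individual_id", "island", "sex", "deploy_year"):
                    fx[col] = tr[col].iloc[0]
                relocated.append(fx)
            tracks = relocated
        timing["geolocate"] = time.perf_counter() - t0

        # ----------------------------------------------- filter + QC + segment
        stage = "segment"
        t0 = time.perf_counter()
        grid = coast.rasterize(config.resolution_deg)
        colonies = {c.name: (c.lon, c.lat) for c in synthetic.DEFAULT_COLONIES}
        n_qc_reject = n_no_migration = n_open = 0
        rows = []
        for k, tr in enumerate(tracks):
            tr = tr.copy()
            if "date" not in tr.columns:
                ts = pd.to_datetime(tr["timestamp"])
                if ts.dt.tz is not None:
                    ts = ts.dt.tz_localize(None)
                tr["date"] = ts.dt.normalize()
            flagged = geolocate.filter_fixes(
                tr,
                equinox_window_days=config.equinox_window_days,
                max_speed_kmh=config.max_speed_kmh,
                bbox=config.bbox,
            )
            kept = flagged[flagged["flag"] == "ok"].reset_index(drop=True)
            accept, reasons = geolocate.qc_track(
                flagged, kept["date"].min() if len(kept) else pd.Timestamp("2000-01-01"),
                min_fixes=config.min_fixes,
            )
            if not accept:
                n_qc_reject += 1
                continue
            bounds = segment.segment_track(kept, buffer, window=config.rolling_window)
            if bounds is None:
                n_no_migration += 1
                continue
            if bounds.open_ended:
                n_open += 1
                continue
            truth_meta = tracks[k].attrs.get("truth", {})
            colony_name = truth_meta.get("colony")
            colony_ll = colonies.get(colony_name, next(iter(colonies.values())))
            kept2 = kept.rename(columns={"date": "obs_date"})
            kept2["timestamp"] = pd.to_datetime(kept2["obs_date"])
            row = metrics.summarize_migration(
                kept2, bounds, colony_ll, grid=grid, mask=coast,
                meta=dict(
                    individual_id=tr["individual_id"].iloc[0],
                    island=tr["island"].iloc[0],
                    sex=tr["sex"].iloc[0],
                    year=int(tr["deploy_year"].iloc[0]),
                ),
            )
            row["departure_date"] = bounds.departure_date
            row["return_date"] = bounds.return_date
            rows.append(row)
        summaries = pd.DataFrame(rows)
        timing["segment+metrics"] = time.perf_counter() - t0
        report += [
            f"rejected by QC: {n_qc_reject}",
            f"no migration fixes: {n_no_migration}",
            f"open-ended (no return): {n_open}",
            f"retained migrations: {len(summaries)}",
            f"individuals: {summaries['individual_id'].nunique() if len(summaries) else 0}",
        ]
        _write_csv(summaries, out / "summaries.csv", cfg_hash)

        # ----------------------------------------------------------- inference
        stage = "infer"
        t0 = time.perf_counter()
        results: dict = {}
        if len(summaries) >= 20:
            summaries = summaries.copy()
            summaries["area"] = infer.batch_and_classify(
                summaries, batches=config.batches, seed=config.seed
            )
            if sst is not None:
                sst_map = dict(zip(sst["year"], sst["sst_c"]))
                summaries["sst"] = summaries["year"].map(sst_map)
            _write_csv(
                summaries[["individual_id", "year", "median_lat", "area"]],
                out / "area_assignments.csv",
                cfg_hash,
            )
            effects = []
            if "sst" in summaries.columns:
                lat = infer.decompose_effect(
                    summaries, "median_lat", "sst",
                    extra_terms=("C(area)", "C(sex)"),
                    n_boot=config.n_boot, seed=config.seed,
                )
                results["latitude"] = lat
            spd = infer.decompose_effect(
                summaries.dropna(subset=["return_speed", "outbound_speed"]),
                "return_speed", "max_lat",
                extra_terms=("outbound_speed", "C(area)", "C(sex)"),
                n_boot=config.n_boot, seed=config.seed + 1,
            )
            results["speed"] = spd
            summaries["return_doy_obs"] = pd.to_datetime(
                summaries["return_date"]
            ).dt.dayofyear.astype(float)
            phen = infer.decompose_effect(
                summaries.dropna(subset=["return_doy_obs"]),
                "return_doy_obs", "max_lat",
                extra_terms=("C(area)", "C(island)"),
                n_boot=config.n_boot, seed=config.seed + 2,
            )
            results["return_date"] = phen
            for name, dec in results.items():
                effects.append(
                    dict(
                        model=name,
                        between=dec.between_slope,
                        between_lo=dec.between_ci[0], between_hi=dec.between_ci[1],
                        within=dec.within_slope,
                        within_lo=dec.within_ci[0], within_hi=dec.within_ci[1],
                        diff_lo=dec.difference_ci[0], diff_hi=dec.difference_ci[1],
                        lrt_between_chi2=dec.lrt_between[0], lrt_between_p=dec.lrt_between[2],
                        lrt_within_chi2=dec.lrt_within[0], lrt_within_p=dec.lrt_within[2],
                    )
                )
            _write_csv(pd.DataFrame(effects), out / "effects.csv", cfg_hash)
            trend = infer.first_track_trend(summaries, sst=sst if config.simulate else None)
            results["first_track"] = trend
            report.append(
                f"first-track trend: {trend['slope_per_year']:+.4f} deg/yr "
                f"(se {trend['slope_se']:.4f})"
            )
            for name, dec in results.items():
                if not isinstance(dec, infer.EffectDecomposition):
                    continue
                report.append(
                    f"{name}: between {dec.between_slope:+.3f} "
                    f"[{dec.between_ci[0]:+.3f}, {dec.between_ci[1]:+.3f}], "
                    f"within {dec.within_slope:+.3f} "
                    f"[{dec.within_ci[0]:+.3f}, {dec.within_ci[1]:+.3f}]"
                )
        else:
            report.append("inference skipped: fewer than 20 retained migrations")
        timing["infer"] = time.perf_counter() - t0
    except Exception as exc:
        report.append(f"FAILED at stage {stage}: {exc}")
        (out / "report.txt").write_text("\n".join(report) + "\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    report.append("timings: " + ", ".join(f"{k} {v:.1f}s" for k, v in timing.items()))
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return {
        "summaries": summaries,
        "results": results,
        "report": report,
        "counts": dict(
            input=len(tracks),
            qc_reject=n_qc_reject,
            no_migration=n_no_migration,
            open_ended=n_open,
            retained=len(summaries),
        ),
    }
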