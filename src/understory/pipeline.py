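"""End-to-end pipeline: simulate → harmonize → features → train → predict →
traits → variogram → spatial assessment, with a reproducibility manifest.

One global seed deterministically derives every stage seed, so a fixed
configuration reproduces bit-identical outputs; the manifest records
settings, per-stage row/cell counts and a SHA-256 hash of every file
written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import Raster, write_ascii_grid
from .synthetic import (GenerativeParams, generate_predictor_stack,
                        sample_sensor_network, generate_logger_series,
                        write_logger_csv)
from .harmonize import harmonize_network, read_logger_csv, DEFAULT_COVERAGE_THRESHOLD
from .features import extract_at_points, stack_climatology, forest_mask, DEFAULT_TCC_THRESHOLD
from .model import Hyperparams, fit_bagging, cross_validate, predict_raster
from .traits import temperature_offset, diurnal_range, zone_raster, zonal_summary
from .variogram import compare_heterogeneity
from .assessment import fit_pc_space, interpolation_map, buffered_loocv

logger = logging.getLogger(__name__)

STAGES = ("simulate", "harmonize", "features", "train", "predict",
          "traits", "variogram", "assess")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        self.stage, self.code = stage, code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; defaults equal the documented decisions."""

    out_dir: str = "understory_run"
    # synthetic world
    extent: tuple[float, float, float, float] = (-2.0, -1.0, 20.0, 21.0)
    cell_size: float = 0.02
    months: int = 3
    start: str = "2020-01-01"
    n_sensors: int = 120
    forest_fraction: float = 0.8
    generative: dict = field(default_factory=dict)   # GenerativeParams overrides
    # harmonization
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
    # features / mask
    tcc_threshold: float = DEFAULT_TCC_THRESHOLD
    # model
    hyperparams: dict = field(default_factory=lambda: {
        "min_leaf_size": 4, "n_learners": 100, "n_predictors_sampled": 6})
    cv_folds: int = 5
    # variogram
    vg_direction: float = 90.0
    vg_tolerance: float = 22.5
    vg_max_lag: float = 110.0
    vg_bin_width: float = 5.0
    # assessment
    variance_threshold: float = 0.93
    cv_radii: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0)
    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("extent", "cv_radii"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed (< 2^31) from the global one."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config),
                      "stages": {}, "files": {}}
    t_all = time.time()

    def finish_stage(name: str, info: dict, files: list[Path]):
        info["seconds"] = round(time.time() - t_stage, 3)
        manifest["stages"][name] = info
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
        logger.info("stage %-10s done in %.2fs", name, info["seconds"])

    # --- simulate -----------------------------------------------------------
    t_stage = time.time()
    try:
        gen = GenerativeParams(seed=stage_seed(config.seed, "generate"), **config.generative)
        stack = generate_predictor_stack(config.extent, config.cell_size,
                                         seed=stage_seed(config.seed, "stack"),
                                         forest_fraction=config.forest_fraction)
        network = sample_sensor_network(stack, config.n_sensors,
                                        seed=stage_seed(config.seed, "network"),
                                        tcc_threshold=config.tcc_threshold)
        series = generate_logger_series(network, stack, gen, config.start, config.months)
        loggers_path = out / "loggers.csv"
        write_logger_csv(series, loggers_path)
        network_path = out / "network.csv"
        network.to_csv(network_path, index=False)
        raster_files = []
        for name in ("elevation", "slope", "aspect", "lai", "fapar", "canopy_height", "tcc"):
            p = write_ascii_grid(stack.predictor_raster(name), out / f"{name}.asc")
            raster_files.append(p)
        finish_stage("simulate", {"n_sensors": len(network),
                                  "grid": list(stack.grid.shape)},
                     [loggers_path, network_path] + raster_files)
    except Exception as exc:
        raise PipelineError("simulate", "generation-failed", str(exc)) from exc

    # --- harmonize ----------------------------------------------------------
    t_stage = time.time()
    try:
        obs = {sid: df[["timestamp_utc", "t_air_c"]] for sid, df in series.items()}
        monthly = harmonize_network(obs, network, coverage_threshold=config.coverage_threshold)
        monthly_path = out / "monthly.csv"
        monthly.to_csv(monthly_path, index=False, float_format="%.6f")
        finish_stage("harmonize", {"n_rows": len(monthly),
                                   "n_valid": int(monthly["valid"].sum())}, [monthly_path])
    except Exception as exc:
        raise PipelineError("harmonize", "aggregation-failed", str(exc)) from exc

    # --- features -----------------------------------------------------------
    t_stage = time.time()
    try:
        tables = {}
        files = []
        for scale in ("daily", "day", "night"):
            tab = extract_at_points(stack, network, monthly, scale,
                                    tcc_threshold=config.tcc_threshold)
            if tab.empty:
                raise ValueError(f"no training rows for time scale {scale!r}")
            tables[scale] = tab
            p = out / f"training_{scale}.csv"
            tab.to_csv(p, index=False, float_format="%.6f")
            files.append(p)
        finish_stage("features", {s: len(t) for s, t in tables.items()}, files)
    except Exception as exc:
        raise PipelineError("features", "extraction-failed", str(exc)) from exc

    # --- train --------------------------------------------------------------
    t_stage = time.time()
    try:
        hp = Hyperparams(seed=stage_seed(config.seed, "train"), **config.hyperparams)
        models, cv_report = {}, {}
        for scale, tab in tables.items():
            models[scale] = fit_bagging(tab, hp)
            cv = cross_validate(tab, hp, k=min(config.cv_folds, len(tab)),
                                seed=stage_seed(config.seed, f"cv-{scale}"))
            cv_report[scale] = {"rmse": cv["rmse_mean"], "r2": cv["r2"]}
        cv_path = out / "cv_report.json"
        with open(cv_path, "w") as fh:
            json.dump(cv_report, fh, indent=1, sort_keys=True)
        finish_stage("train", cv_report, [cv_path])
    except Exception as exc:
        raise PipelineError("train", "fit-failed", str(exc)) from exc

    # --- predict ------------------------------------------------------------
    t_stage = time.time()
    try:
        start = pd.Timestamp(config.start)
        months_list = [((start.month - 1 + i) % 12) + 1 for i in range(config.months)]
        surfaces: dict[tuple[str, int], Raster] = {}
        files = []
        for scale in ("daily", "day", "night"):
            for month in months_list:
                ras = predict_raster(models[scale], stack, month, time_scale=scale,
                                     tcc_threshold=config.tcc_threshold)
                surfaces[(scale, month)] = ras
                p = write_ascii_grid(ras, out / f"t_under_{scale}_m{month:02d}.asc")
                files.append(p)
        finish_stage("predict", {"n_surfaces": len(surfaces)}, files)
    except Exception as exc:
        raise PipelineError("predict", "prediction-failed", str(exc)) from exc

    # --- traits -------------------------------------------------------------
    t_stage = time.time()
    try:
        clim = stack_climatology(stack)
        mask = forest_mask(stack.tcc, config.tcc_threshold)
        zones = zone_raster(stack.predictor_raster("elevation"), mask)
        month0 = months_list[0]
        nodata = surfaces[("daily", month0)].nodata
        files, zonal_frames = [], []
        summary_stats = {}
        for month in months_list:
            t_open = Raster(stack.grid, np.where(mask, clim["daily"][month - 1], nodata), nodata)
            d_t = temperature_offset(surfaces[("daily", month)], t_open)
            r_t = diurnal_range(surfaces[("day", month)], surfaces[("night", month)])
            macro_rt = Raster(stack.grid,
                              np.where(mask, clim["day"][month - 1] - clim["night"][month - 1], nodata),
                              nodata)
            files.append(write_ascii_grid(d_t, out / f"dT_daily_m{month:02d}.asc"))
            files.append(write_ascii_grid(r_t, out / f"rT_m{month:02d}.asc"))
            zonal_frames.append(zonal_summary({"dT_daily": d_t, "rT": r_t}, zones, month))
            summary_stats[month] = {
                "mean_dT_daily": float(d_t.valid_values().mean()),
                "mean_rT_under": float(r_t.valid_values().mean()),
                "mean_rT_open": float(macro_rt.valid_values().mean()),
            }
        zonal = pd.concat(zonal_frames, ignore_index=True)
        zp = out / "zonal_summary.csv"
        zonal.to_csv(zp, index=False, float_format="%.6f")
        files.append(zp)
        finish_stage("traits", {"months": summary_stats,
                                "n_zones": int(zonal["zone"].nunique())}, files)
    except Exception as exc:
        raise PipelineError("traits", "traits-failed", str(exc)) from exc

    # --- variogram ----------------------------------------------------------
    t_stage = time.time()
    try:
        month = months_list[0]
        t_open = Raster(stack.grid, np.where(mask, clim["daily"][month - 1], nodata), nodata)
        comp = compare_heterogeneity(surfaces[("daily", month)], t_open,
                                     direction=config.vg_direction,
                                     tolerance=config.vg_tolerance,
                                     max_lag=config.vg_max_lag,
                                     bin_width=config.vg_bin_width)
        vg_path = out / "variogram.json"
        with open(vg_path, "w") as fh:
            json.dump({
                "under": {"sill": comp.fit_under.sill, "d": comp.fit_under.minimum_distance,
                          "nugget": comp.fit_under.nugget},
                "open": {"sill": comp.fit_open.sill, "d": comp.fit_open.minimum_distance,
                         "nugget": comp.fit_open.nugget},
                "d_ratio": comp.d_ratio,
            }, fh, indent=1, sort_keys=True)
        finish_stage("variogram", {"d_ratio": comp.d_ratio}, [vg_path])
    except Exception as exc:
        raise PipelineError("variogram", "variogram-failed", str(exc)) from exc

    # --- assess -------------------------------------------------------------
    t_stage = time.time()
    try:
        table = tables["daily"]
        space = fit_pc_space(table, config.variance_threshold)
        maps = [interpolation_map(space, stack, table, m, "daily", config.tcc_threshold)
                for m in months_list]
        from .assessment import aggregate_interpolation
        annual = aggregate_interpolation(maps)
        files = [write_ascii_grid(annual, out / "interpolation_degree.asc")]
        cv_res = buffered_loocv(table, list(config.cv_radii), hp,
                                seed=stage_seed(config.seed, "buffered-cv"))
        p = out / "buffered_cv.csv"
        cv_res.table.to_csv(p, index=False, float_format="%.6f")
        files.append(p)
        finish_stage("assess", {"k": space.k,
                                "n_pc_pairs": space.k * (space.k - 1) // 2,
                                "mean_interpolation": float(annual.valid_values().mean()),
                                "stabilization_radius": cv_res.stabilization_radius}, files)
    except Exception as exc:
        raise PipelineError("assess", "assessment-failed", str(exc)) from exc

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["files"]["manifest.json"] = None  # self-reference excluded from hashing
    return manifest
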