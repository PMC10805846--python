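"""Predictor harmonization, macroclimate climatology, masking, and feature extraction.

Builds the training table that links each sensor-month response (T_daily,
T_dt or T_nt) to the nine predictors — elevation, slope, aspect, LAI, FAPAR,
canopy height, and the three macroclimate variables (2-m air temperature,
precipitation, net solar radiation) — sampled at the raster cell containing
the sensor.  Rasters of differing resolution are harmonized by nearest
neighbour only; cells below the tree-canopy-cover threshold are masked as
non-forest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import Grid, Raster, same_grid
from .harmonize import DAY_START_HOUR, DAY_END_HOUR
from .synthetic import PredictorStack, PREDICTOR_NAMES

logger = logging.getLogger(__name__)

DEFAULT_TCC_THRESHOLD = 40.0  # percent canopy cover separating forest from non-forest

TIME_SCALES = ("daily", "day", "night")


class CoverageError(ValueError):
    """Source raster does not cover the target grid."""


def _nearest_indices(src: Grid, dst: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Row/col index arrays mapping each dst cell centre to its nearest src cell centre."""
    dst_lats = dst.cell_center_lats()
    dst_lons = dst.cell_center_lons()
    half = src.cell_size / 2.0
    if (dst_lats.max() > src.lat_max + half or dst_lats.min() < src.lat_min - half
            or dst_lons.max() > src.lon_max + half or dst_lons.min() < src.lon_min - half):
        raise CoverageError("target grid extends beyond the source raster extent")
    src_lats = src.cell_center_lats()
    src_lons = src.cell_center_lons()
    # regular grids: nearest centre found by rounding in index space
    rows = np.clip(np.round((src_lats[0] - dst_lats) / src.cell_size), 0, src.nrows - 1).astype(int)
    cols = np.clip(np.round((dst_lons - src_lons[0]) / src.cell_size), 0, src.ncols - 1).astype(int)
    return rows, cols


def resample_nearest(raster: Raster, target_grid: Grid) -> Raster:
    """Resample onto ``target_grid``: each cell takes the nearest source value.

    No value interpolation happens, so categorical-like rasters (e.g. canopy
    cover classes) keep only values present in the source.  Identical grids
    return an identical copy.
    """
    if same_grid(raster.grid, target_grid):
        return Raster(target_grid, raster.values.copy(), raster.nodata)
    rows, cols = _nearest_indices(raster.grid, target_grid)
    values = raster.values[np.ix_(rows, cols)]
    return Raster(target_grid, values, raster.nodata)


def forest_mask(tcc: Raster | np.ndarray, threshold: float = DEFAULT_TCC_THRESHOLD) -> np.ndarray:
    """Boolean mask, True where tree canopy cover >= threshold (inclusive)."""
    values = tcc.values if isinstance(tcc, Raster) else np.asarray(tcc)
    return values >= threshold


def macro_climatology(hourly_local: pd.DataFrame,
                      value_col: str = "value") -> pd.DataFrame:
    """Multi-year hourly series -> per-calendar-month climatological means.

    Computes, for each calendar month, the daily / day-time / night-time mean
    within each year (the same local-hour windows as the logger
    harmonization) and then averages those across years, so each year
    contributes equally regardless of record length.

    Returns a DataFrame indexed by month (1-12) with columns daily, day, night.
    """
    df = hourly_local.copy()
    t = pd.to_datetime(df["timestamp_local"])
    if len(df) == 0:
        raise ValueError("macro_climatology requires at least one record")
    df["year"] = t.dt.year
    df["month"] = t.dt.month
    hour = t.dt.hour
    df["is_day"] = (hour >= DAY_START_HOUR) & (hour < DAY_END_HOUR)
    per_year = df.groupby(["month", "year"]).apply(
        lambda g: pd.Series({
            "daily": g[value_col].mean(),
            "day": g.loc[g["is_day"], value_col].mean(),
            "night": g.loc[~g["is_day"], value_col].mean(),
        }), include_groups=False)
    clim = per_year.groupby(level="month").mean()
    clim.index.name = "month"
    return clim


def stack_climatology(stack: PredictorStack) -> dict[str, np.ndarray]:
    """Per-time-scale monthly macro temperature fields from a stack's climatology.

    Returns {'daily'|'day'|'night': array (12, rows, cols)} of macro_t means
    over the corresponding local-hour windows.
    """
    hours = np.arange(24)
    day = (hours >= DAY_START_HOUR) & (hours < DAY_END_HOUR)
    return {
        "daily": stack.macro_t.mean(axis=1),
        "day": stack.macro_t[:, day].mean(axis=1),
        "night": stack.macro_t[:, ~day].mean(axis=1),
    }


def extract_at_points(stack: PredictorStack, network: pd.DataFrame,
                      monthly: pd.DataFrame, time_scale: str,
                      tcc_threshold: float = DEFAULT_TCC_THRESHOLD,
                      drop_invalid: bool = True) -> pd.DataFrame:
    """Join sensor-month responses with the nine predictors at the sensor cell.

    ``monthly`` is the output of :func:`understory.harmonize.harmonize_network`.
    ``time_scale`` selects the response: 'daily' -> t_daily, 'day' -> t_dt,
    'night' -> t_nt.  Sensors on non-forest (masked) cells are excluded with a
    logged count; sensors outside the stack raise a KeyError naming them.
    """
    if time_scale not in TIME_SCALES:
        raise ValueError(f"time_scale must be one of {TIME_SCALES}, got {time_scale!r}")
    response_col = {"daily": "t_daily", "day": "t_dt", "night": "t_nt"}[time_scale]
    mask = forest_mask(stack.tcc, tcc_threshold)
    clim = stack_climatology(stack)[time_scale]

    cell_by_sensor: dict[str, tuple[int, int]] = {}
    masked_out = []
    for row in network.itertuples(index=False):
        try:
            r, c = stack.grid.index_of(row.lat, row.lon)
        except KeyError as exc:
            raise KeyError(f"sensor {row.sensor_id!r} is outside the predictor stack: {exc}") from exc
        if not mask[r, c]:
            masked_out.append(row.sensor_id)
            continue
        cell_by_sensor[row.sensor_id] = (r, c)
    if masked_out:
        logger.info("extract_at_points: excluded %d sensors on non-forest cells: %s",
                    len(masked_out), ", ".join(masked_out[:10]))

    lat_by_sensor = dict(zip(network["sensor_id"], network["lat"]))
    lon_by_sensor = dict(zip(network["sensor_id"], network["lon"]))
    rows = []
    for rec in monthly.itertuples(index=False):
        if rec.sensor_id not in cell_by_sensor:
            continue
        if drop_invalid and not rec.valid:
            continue
        r, c = cell_by_sensor[rec.sensor_id]
        m = int(rec.month) - 1
        rows.append({
            "sensor_id": rec.sensor_id,
            "year": int(rec.year), "month": int(rec.month),
            "lat": lat_by_sensor[rec.sensor_id], "lon": lon_by_sensor[rec.sensor_id],
            "response": getattr(rec, response_col),
            "elevation": stack.elevation[r, c],
            "slope": stack.slope[r, c],
            "aspect": stack.aspect[r, c],
            "lai": stack.lai[r, c],
            "fapar": stack.fapar[r, c],
            "canopy_height": stack.canopy_height[r, c],
            "macro_t": clim[m, r, c],
            "macro_precip": stack.macro_precip[m, r, c],
            "macro_rad": stack.macro_rad[m, r, c],
        })
    table = pd.DataFrame(rows, columns=["sensor_id", "year", "month", "lat", "lon",
                                        "response"] + PREDICTOR_NAMES)
    if table[PREDICTOR_NAMES].isna().any().any():
        raise ValueError("missing predictor values in training table")
    return table
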