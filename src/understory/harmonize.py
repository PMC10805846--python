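"""Harmonize raw 15-minute logger records into monthly local-time summaries.

Raw understory loggers sample every 15 minutes in UTC.  The pipeline averages
them to clock hours, shifts to local solar time using only the longitude
(one whole-hour offset of round(lon / 15), applied identically to loggers and
macroclimate so that offsets stay coherent), and then reduces each calendar
month to three responses:

* ``t_daily`` — mean of all hourly records in the month,
* ``t_dt``    — day-time mean, local hour in [06, 18),
* ``t_nt``    — night-time mean, local hour in [18, 24) or [0, 6).

Hours without samples stay missing (no imputation); a per-month ``coverage``
fraction (hours present / hours expected) is reported and months below the
threshold are *flagged*, never silently dropped.
"""

from __future__ import annotations

import calendar
import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAY_START_HOUR = 6     # inclusive
DAY_END_HOUR = 18      # exclusive
DEFAULT_COVERAGE_THRESHOLD = 0.9

PLAUSIBLE_RANGE_C = (-20.0, 60.0)


def utc_offset_hours(lon: float) -> int:
    """Longitude-derived whole-hour offset, rounded half away from zero.

    lon=120 -> +8; lon=-67.5 -> -5 (4.5 rounds away from zero).
    """
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside [-180, 180]")
    return int(math.copysign(math.floor(abs(lon) / 15.0 + 0.5), lon))


def aggregate_to_hourly(samples: pd.DataFrame,
                        time_col: str = "timestamp_utc",
                        value_col: str = "t_air_c") -> pd.DataFrame:
    """Average sub-hourly samples into clock hours.

    Each output row is the arithmetic mean of all samples whose timestamp
    falls in [h, h+1); hours with no samples are absent from the output.
    Already-hourly input passes through unchanged (idempotent).
    """
    if samples.empty:
        logger.warning("aggregate_to_hourly: empty input series")
        return pd.DataFrame({time_col: pd.Series(dtype="datetime64[ns]"),
                             value_col: pd.Series(dtype=float)})
    df = samples[[time_col, value_col]].copy()
    df[time_col] = pd.to_datetime(df[time_col])
    df = df.sort_values(time_col)
    hours = df[time_col].dt.floor("h")
    out = df.groupby(hours, sort=True)[value_col].mean().reset_index()
    return out


def to_local_time(hourly: pd.DataFrame, lon: float,
                  time_col: str = "timestamp_utc") -> pd.DataFrame:
    """Shift hourly timestamps to local solar time by round(lon/15) hours.

    The applied shift is recorded in ``out.attrs['utc_offset_hours']`` and the
    time column is renamed ``timestamp_local``.
    """
    shift = utc_offset_hours(lon)
    out = hourly.copy()
    out[time_col] = pd.to_datetime(out[time_col]) + pd.Timedelta(hours=shift)
    out = out.rename(columns={time_col: "timestamp_local"})
    out.attrs["utc_offset_hours"] = shift
    return out


def _expected_hours(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1] * 24


def monthly_summaries(hourly_local: pd.DataFrame,
                      value_col: str = "t_air_c",
                      coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> pd.DataFrame:
    """Reduce an hourly local-time series to per-month T_daily / T_dt / T_nt.

    Returns a DataFrame with columns year, month, t_daily, t_dt, t_nt,
    coverage, valid.  ``valid`` is False when the month lacks either day or
    night records entirely or its coverage falls below the threshold; such
    months are flagged, not removed.
    """
    df = hourly_local.copy()
    t = pd.to_datetime(df["timestamp_local"])
    df["year"] = t.dt.year
    df["month"] = t.dt.month
    hour = t.dt.hour
    df["is_day"] = (hour >= DAY_START_HOUR) & (hour < DAY_END_HOUR)

    rows = []
    for (year, month), grp in df.groupby(["year", "month"], sort=True):
        day_vals = grp.loc[grp["is_day"], value_col]
        night_vals = grp.loc[~grp["is_day"], value_col]
        coverage = len(grp) / _expected_hours(int(year), int(month))
        t_dt = day_vals.mean() if len(day_vals) else np.nan
        t_nt = night_vals.mean() if len(night_vals) else np.nan
        valid = (len(day_vals) > 0 and len(night_vals) > 0
                 and coverage >= coverage_threshold)
        rows.append({"year": int(year), "month": int(month),
                     "t_daily": grp[value_col].mean(),
                     "t_dt": t_dt, "t_nt": t_nt,
                     "coverage": min(coverage, 1.0), "valid": valid})
    return pd.DataFrame(rows, columns=["year", "month", "t_daily", "t_dt", "t_nt",
                                       "coverage", "valid"])


def harmonize_sensor(samples: pd.DataFrame, lon: float,
                     coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                     value_col: str = "t_air_c") -> pd.DataFrame:
    """15-min UTC samples -> hourly -> local time -> monthly summaries."""
    hourly = aggregate_to_hourly(samples, value_col=value_col)
    local = to_local_time(hourly, lon)
    return monthly_summaries(local, value_col=value_col,
                             coverage_threshold=coverage_threshold)


def harmonize_network(series: dict[str, pd.DataFrame], network: pd.DataFrame,
                      coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                      value_col: str = "t_air_c") -> pd.DataFrame:
    """Harmonize every sensor; returns rows keyed by sensor_id, year, month."""
    lon_by_id = dict(zip(network["sensor_id"], network["lon"]))
    frames = []
    for sid, samples in series.items():
        if sid not in lon_by_id:
            raise KeyError(f"sensor {sid!r} missing from the network table")
        monthly = harmonize_sensor(samples, lon_by_id[sid],
                                   coverage_threshold=coverage_threshold,
                                   value_col=value_col)
        monthly.insert(0, "sensor_id", sid)
        frames.append(monthly)
    if not frames:
        return pd.DataFrame(columns=["sensor_id", "year", "month", "t_daily",
                                     "t_dt", "t_nt", "coverage", "valid"])
    return pd.concat(frames, ignore_index=True)


def read_logger_csv(path) -> dict[str, pd.DataFrame]:
    """Read a combined logger CSV; rows are re-sorted by time per sensor.

    Raises ValueError naming the offending line for non-ISO timestamps.
    """
    df = pd.read_csv(path, dtype={"sensor_id": str})
    try:
        df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"], format="ISO8601")
    except (ValueError, TypeError):
        ts = pd.to_datetime(df["timestamp_utc"], format="ISO8601", errors="coerce")
        bad = int(np.argmax(ts.isna().to_numpy()))
        raise ValueError(f"{path}: non-ISO-8601 timestamp "
                         f"{df['timestamp_utc'].iloc[bad]!r} on data line {bad + 2}")
    lo, hi = PLAUSIBLE_RANGE_C
    n_bad = int(((df["t_air_c"] < lo) | (df["t_air_c"] > hi)).sum())
    if n_bad:
        logger.warning("%s: %d records outside plausible range %s °C", path, n_bad, PLAUSIBLE_RANGE_C)
    out = {}
    for sid, grp in df.groupby("sensor_id", sort=True):
        out[sid] = grp.sort_values("timestamp_utc").reset_index(drop=True).drop(columns=["sensor_id"])
    return out
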