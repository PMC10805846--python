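"""Synthetic tropical world: terrain, canopy, macroclimate and logger networks.

This module fabricates everything the real study measures — gridded
biophysical predictors, a coarse hourly macroclimate climatology, a network
of understory temperature loggers, and their 15-minute records — from a
*known* generative model, so that every downstream stage (harmonization,
model fitting, thermal traits, geostatistics, spatial assessment) can be
verified against ground truth.

The generative model for the true understory air temperature at a sensor is
deliberately linear in the predictors::

    T_true(t) = macro_t(month, local hour)          # open-air climatology
              + base_offset                          # mean under-canopy offset
              + lapse_rate * elevation / 1000        # °C per km, negative
              - canopy_damping * LAI * diurnal_dev   # canopy damps the diurnal cycle
              + night_warming * FAPAR * is_night     # longwave retention at night

where ``diurnal_dev`` is the macroclimate's deviation from its own daily
mean.  Observed records add a spatially correlated monthly noise field
(weather) and white 15-minute noise (instrument).  The noiseless truth is
returned alongside the observations, so parameter-recovery tests have a
well-defined target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid, Raster, KM_PER_DEG

TROPIC_LAT = 23.45

#: canonical ordering of the nine logical model predictors
PREDICTOR_NAMES = ["elevation", "slope", "aspect", "lai", "fapar",
                   "canopy_height", "macro_t", "macro_precip", "macro_rad"]


class DomainError(ValueError):
    """Requested geometry falls outside the tropical study domain."""


@dataclass
class GenerativeParams:
    """Coefficients of the synthetic understory-temperature model.

    lapse_rate : °C per km of elevation (negative = cooling with altitude)
    canopy_damping : fractional reduction of the diurnal deviation per LAI unit
    night_warming : °C added at night per unit FAPAR (canopy longwave retention)
    base_offset : mean understory-minus-open offset, °C
    noise_sd : white instrument noise sd per 15-min sample, °C
    spatial_range : e-folding range of the correlated monthly noise field, km
    spatial_sill : variance of the correlated monthly noise field, °C²
    """

    lapse_rate: float = -6.5
    canopy_damping: float = 0.05
    night_warming: float = 0.5
    base_offset: float = -1.0
    noise_sd: float = 0.3
    spatial_range: float = 50.0
    spatial_sill: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be > 0")
        if self.spatial_sill < 0:
            raise ValueError("spatial_sill must be >= 0")


@dataclass
class PredictorStack:
    """Co-registered predictor rasters plus the hourly macroclimate climatology.

    2-D fields have shape ``grid.shape``; ``macro_t`` has shape (12, 24, rows,
    cols) indexed by (calendar month - 1, local hour of day); ``macro_precip``
    and ``macro_rad`` have shape (12, rows, cols).  Macroclimate is generated
    on a coarser native lattice and expanded to the fine grid by nearest
    neighbour, mirroring how a ~0.1° reanalysis pixel is joined to ~30 m
    predictors.
    """

    grid: Grid
    elevation: np.ndarray
    slope: np.ndarray
    aspect: np.ndarray
    lai: np.ndarray
    fapar: np.ndarray
    canopy_height: np.ndarray
    tcc: np.ndarray
    macro_t: np.ndarray
    macro_precip: np.ndarray
    macro_rad: np.ndarray
    macro_native_factor: int = 1

    def validate(self) -> None:
        shp = self.grid.shape
        for name in ("elevation", "slope", "aspect", "lai", "fapar", "canopy_height", "tcc"):
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shp}")
        if self.macro_t.shape != (12, 24) + shp:
            raise ValueError(f"macro_t shape {self.macro_t.shape} != (12, 24, *{shp})")
        for name in ("macro_precip", "macro_rad"):
            if getattr(self, name).shape != (12,) + shp:
                raise ValueError(f"{name} must be (12, rows, cols)")
        if np.any((self.fapar < 0) | (self.fapar > 1)):
            raise ValueError("fapar outside [0, 1]")
        if np.any((self.tcc < 0) | (self.tcc > 100)):
            raise ValueError("tcc outside [0, 100]")
        if np.any((self.slope < 0) | (self.slope > 90)):
            raise ValueError("slope outside [0, 90]")
        if np.any(self.lai < 0) or np.any(self.canopy_height < 0):
            raise ValueError("lai and canopy_height must be >= 0")

    def predictor_raster(self, name: str) -> Raster:
        return Raster(self.grid, getattr(self, name))

    def macro_t_daily_mean(self) -> np.ndarray:
        """(12, rows, cols) mean of macro_t over the 24 hours."""
        return self.macro_t.mean(axis=1)


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to zero mean, unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    if sd == 0:  # degenerate 1x1 grids
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_grf(grid: Grid, sill: float, range_km: float, seed: int) -> np.ndarray:
    """Zero-mean Gaussian random field with exponential covariance.

    Covariance between cells is ``sill * exp(-d / range_km)`` with d the
    great-circle separation (locally approximated as equirectangular at the
    grid's mean latitude).  Simulated by circulant embedding: the target
    covariance is embedded in a doubly periodic torus, its FFT gives the
    eigenvalues, and a white-noise field is coloured in the spectral domain.
    Small negative embedding eigenvalues are clipped, a standard approximation
    whose variance error is negligible at the ranges used here.

    The corresponding semivariogram is ``sill * (1 - exp(-d / range_km))``:
    sill ``sill``, practical (95 %) range ``3 * range_km``.
    """
    if sill < 0:
        raise ValueError("sill must be >= 0")
    if range_km <= 0:
        raise ValueError("range_km must be > 0")
    if sill == 0:
        return np.zeros(grid.shape)
    nr, nc = grid.shape
    mean_lat = 0.5 * (grid.lat_min + grid.lat_max)
    dy_km = grid.cell_size * KM_PER_DEG
    dx_km = grid.cell_size * KM_PER_DEG * math.cos(math.radians(mean_lat))
    m, n = 2 * nr, 2 * nc
    ii = np.minimum(np.arange(m), m - np.arange(m)) * dy_km
    jj = np.minimum(np.arange(n), n - np.arange(n)) * dx_km
    d = np.hypot(ii[:, None], jj[None, :])
    cov = sill * np.exp(-d / range_km)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    # clipping negative embedding eigenvalues inflates the variance; rescale
    # so the marginal variance is exactly the sill
    realized_var = lam.sum() / (m * n)
    scale = math.sqrt(sill / realized_var) if realized_var > 0 else 0.0
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((m, n))
    coloured = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(white)).real * scale
    return coloured[:nr, :nc]


def generate_predictor_stack(extent: tuple[float, float, float, float],
                             cell_size: float,
                             seed: int,
                             forest_fraction: float = 0.8,
                             macro_factor: int = 5,
                             diurnal_amplitude: float = 4.0,
                             roughness: float = 1.0) -> PredictorStack:
    """Generate a co-registered synthetic predictor stack.

    Parameters
    ----------
    extent
        (lat_min, lat_max, lon_min, lon_max) in decimal degrees; must lie
        within the tropics (|lat| <= 23.45).
    cell_size
        Cell edge in degrees.
    forest_fraction
        Fraction of cells given tree canopy cover >= 40 % (the forest mask).
    macro_factor
        Linear coarsening factor of the macroclimate's native lattice.
    diurnal_amplitude
        Half-range of the open-air diurnal cycle, °C, peaking at 14:00 local.
    roughness
        Divides the spatial correlation scale of terrain and canopy fields;
        1 gives mesoscale relief spanning ~1/5 of the extent, larger values
        give proportionally finer-grained landscapes (used by experiments
        that need predictor fields to decorrelate over short distances).
    """
    if roughness <= 0:
        raise ValueError("roughness must be positive")
    lat_min, lat_max, lon_min, lon_max = extent
    if lat_min >= lat_max or lon_min >= lon_max:
        raise ValueError(f"degenerate extent {extent}")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if max(abs(lat_min), abs(lat_max)) > TROPIC_LAT:
        raise DomainError(f"extent {extent} extends beyond the tropics (|lat| <= {TROPIC_LAT})")

    nrows = max(1, round((lat_max - lat_min) / cell_size))
    ncols = max(1, round((lon_max - lon_min) / cell_size))
    grid = Grid(nrows=nrows, ncols=ncols, lat_min=lat_min, lon_min=lon_min, cell_size=cell_size)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shp = grid.shape
    scale = max(nrows, ncols) / roughness

    # --- terrain: multi-octave smoothed noise, clipped to sea level
    elev = (400.0
            + 320.0 * _smooth_unit_field(rng, shp, sigma=max(scale / 5, 1.5))
            + 130.0 * _smooth_unit_field(rng, shp, sigma=max(scale / 12, 1.0))
            + 45.0 * _smooth_unit_field(rng, shp, sigma=max(scale / 30, 0.6)))
    elev = np.clip(elev, 0.0, None)

    # slope/aspect from the elevation gradient in metric coordinates
    lat_rows = grid.cell_center_lats()
    dy_m = grid.cell_size * 1000.0 * KM_PER_DEG
    dx_m = grid.cell_size * 1000.0 * KM_PER_DEG * np.cos(np.radians(lat_rows))[:, None]
    if nrows > 1:
        g_row = np.gradient(elev, axis=0)
    else:
        g_row = np.zeros(shp)
    if ncols > 1:
        g_col = np.gradient(elev, axis=1)
    else:
        g_col = np.zeros(shp)
    dz_dnorth = -g_row / dy_m          # row index increases southwards
    dz_deast = g_col / dx_m
    slope = np.degrees(np.arctan(np.hypot(dz_dnorth, dz_deast)))
    aspect = (np.degrees(np.arctan2(dz_deast, dz_dnorth)) + 180.0) % 360.0  # downslope facing

    # --- canopy structure: correlated smooth fields
    lai_core = _smooth_unit_field(rng, shp, sigma=max(scale / 8, 1.0))
    lai = np.clip(3.8 + 1.1 * lai_core + 0.4 * _smooth_unit_field(rng, shp, sigma=max(scale / 20, 0.8)), 0.0, 7.0)
    fapar = np.clip(0.10 + 0.115 * lai + 0.04 * _smooth_unit_field(rng, shp, sigma=max(scale / 15, 0.8)), 0.0, 1.0)
    canopy_height = np.clip(5.0 + 3.2 * lai + 2.0 * _smooth_unit_field(rng, shp, sigma=max(scale / 10, 0.8)), 0.5, None)

    # --- tree canopy cover: exactly `forest_fraction` of cells at >= 40 %
    tcc_field = _smooth_unit_field(rng, shp, sigma=max(scale / 7, 1.0))
    q = np.quantile(tcc_field, 1.0 - forest_fraction) if forest_fraction < 1.0 else tcc_field.min()
    tcc = np.clip(40.0 + 30.0 * (tcc_field - q), 0.0, 100.0)

    # --- macroclimate on its coarse native lattice, nearest-expanded
    cr = max(1, math.ceil(nrows / macro_factor))
    cc = max(1, math.ceil(ncols / macro_factor))
    coarse_sigma = max(max(cr, cc) / 4 / roughness, 0.8)
    coarse_anom = _smooth_unit_field(rng, (cr, cc), sigma=coarse_sigma)
    coarse_anom2 = _smooth_unit_field(rng, (cr, cc), sigma=coarse_sigma)
    coarse_lat = lat_max - (np.arange(cr) + 0.5) * (lat_max - lat_min) / cr

    base_t = 26.5 - 0.12 * np.abs(coarse_lat)[:, None] + 1.5 * coarse_anom  # (cr, cc)
    months = np.arange(12)
    peak_month = np.where(coarse_lat < 0, 0.0, 6.0)[:, None]                 # Jan in S, Jul in N
    seas_amp = (0.8 + 1.2 * np.abs(coarse_lat) / TROPIC_LAT)[:, None]
    seas = seas_amp[None] * np.cos(2 * np.pi * (months[:, None, None] - peak_month[None]) / 12.0)  # (12, cr, cc)
    hours = np.arange(24)
    diurnal = diurnal_amplitude * np.cos(2 * np.pi * (hours - 14.0) / 24.0)  # peaks 14:00 local

    macro_t_coarse = (base_t[None, None] + seas[:, None] + diurnal[None, :, None, None])  # (12, 24, cr, cc)
    precip_coarse = np.clip(160.0 + 90.0 * np.cos(2 * np.pi * (months[:, None, None] - (peak_month + 6.0)[None]) / 12.0)
                            + 35.0 * coarse_anom2[None], 0.0, None)
    rad_coarse = np.clip(1.5e7 + 3.0e6 * np.cos(2 * np.pi * (months[:, None, None] - peak_month[None]) / 12.0)
                         + 1.0e6 * coarse_anom[None], 0.0, None)

    def expand(arr):
        out = np.repeat(np.repeat(arr, macro_factor, axis=-2), macro_factor, axis=-1)
        return out[..., :nrows, :ncols]

    stack = PredictorStack(grid=grid, elevation=elev, slope=slope, aspect=aspect,
                           lai=lai, fapar=fapar, canopy_height=canopy_height, tcc=tcc,
                           macro_t=expand(macro_t_coarse),
                           macro_precip=expand(precip_coarse),
                           macro_rad=expand(rad_coarse),
                           macro_native_factor=macro_factor)
    stack.validate()
    return stack


def sample_sensor_network(stack: PredictorStack, n_sensors: int, seed: int,
                          tcc_threshold: float = 40.0) -> pd.DataFrame:
    """Place sensors at the centres of distinct forest-masked cells.

    Returns a DataFrame with columns sensor_id, lat, lon, elevation_at_site.
    """
    forest = np.argwhere(stack.tcc >= tcc_threshold)
    if len(forest) < n_sensors:
        raise ValueError(f"only {len(forest)} forest cells for {n_sensors} sensors")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5e)))
    chosen = forest[rng.choice(len(forest), size=n_sensors, replace=False)]
    lats = stack.grid.cell_center_lats()
    lons = stack.grid.cell_center_lons()
    return pd.DataFrame({
        "sensor_id": [f"S{i:03d}" for i in range(n_sensors)],
        "lat": [lats[r] for r, _ in chosen],
        "lon": [lons[c] for _, c in chosen],
        "elevation_at_site": [stack.elevation[r, c] for r, c in chosen],
    })


def utc_offset_hours(lon: float) -> int:
    """Whole-hour solar offset from longitude, rounded half away from zero."""
    return int(math.copysign(math.floor(abs(lon) / 15.0 + 0.5), lon))


def _month_span(start: pd.Timestamp, months: int) -> list[tuple[int, int]]:
    """(year, month) pairs covering the simulation plus one month each side."""
    first = start - pd.offsets.MonthBegin(2)
    out = []
    t = pd.Timestamp(first.year, first.month, 1)
    for _ in range(months + 3):
        out.append((t.year, t.month))
        t = t + pd.offsets.MonthBegin(1)
    return out


def generate_logger_series(network: pd.DataFrame, stack: PredictorStack,
                           params: GenerativeParams, start: str | pd.Timestamp,
                           months: int) -> dict[str, pd.DataFrame]:
    """Simulate 15-minute logger records for every sensor in the network.

    Returns a dict mapping sensor_id to a DataFrame with columns
    ``timestamp_utc`` (tz-naive UTC), ``t_air_c`` (observed, with noise) and
    ``t_true_c`` (the noiseless generative truth).  Timestamps span
    ``months`` calendar months from ``start`` at 15-minute cadence.
    """
    if months < 1:
        raise ValueError("months must be >= 1")
    start = pd.Timestamp(start)
    end = start + pd.offsets.MonthBegin(months) if start.day == 1 else start + pd.DateOffset(months=months)
    ts = pd.date_range(start, end, freq="15min", inclusive="left")

    ss = np.random.SeedSequence((params.seed, 0xA11))
    month_keys = _month_span(start, months)
    noise_seeds = ss.generate_state(len(month_keys) + len(network))
    spatial_fields = {}
    for i, key in enumerate(month_keys):
        if params.spatial_sill > 0:
            spatial_fields[key] = generate_grf(stack.grid, params.spatial_sill,
                                               params.spatial_range, int(noise_seeds[i]))
        else:
            spatial_fields[key] = np.zeros(stack.grid.shape)

    mt_daily = stack.macro_t_daily_mean()  # (12, rows, cols)
    out: dict[str, pd.DataFrame] = {}
    for si, row in enumerate(network.itertuples(index=False)):
        r, c = stack.grid.index_of(row.lat, row.lon)  # KeyError if off-grid
        shift = utc_offset_hours(row.lon)
        local = ts + pd.Timedelta(hours=shift)
        m_idx = local.month.to_numpy() - 1
        h_idx = local.hour.to_numpy()
        mt_cell = stack.macro_t[:, :, r, c]          # (12, 24)
        macro = mt_cell[m_idx, h_idx]
        dev = macro - mt_daily[m_idx, r, c]
        night = ((h_idx < 6) | (h_idx >= 18)).astype(float)
        truth = (macro
                 + params.base_offset
                 + params.lapse_rate * stack.elevation[r, c] / 1000.0
                 - params.canopy_damping * stack.lai[r, c] * dev
                 + params.night_warming * stack.fapar[r, c] * night)
        spatial = np.array([spatial_fields[(y, m)][r, c]
                            for y, m in zip(local.year.to_numpy(), local.month.to_numpy())])
        rng = np.random.default_rng(int(noise_seeds[len(month_keys) + si]))
        white = rng.normal(0.0, params.noise_sd, size=len(ts)) if params.noise_sd > 0 else 0.0
        obs = truth + spatial + white
        out[row.sensor_id] = pd.DataFrame({
            "timestamp_utc": ts,
            "t_air_c": obs,
            "t_true_c": truth,
        })
    return out


def write_logger_csv(series: dict[str, pd.DataFrame], path, include_truth: bool = False) -> None:
    """Write all logger series to one CSV (sensor_id, timestamp_utc, t_air_c[, t_true_c])."""
    frames = []
    for sid, df in series.items():
        f = df.copy()
        f.insert(0, "sensor_id", sid)
        if not include_truth:
            f = f.drop(columns=["t_true_c"])
        frames.append(f)
    allf = pd.concat(frames, ignore_index=True)
    allf["timestamp_utc"] = allf["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    allf.to_csv(path, index=False)
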