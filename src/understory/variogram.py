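"""Spatial heterogeneity via directional semivariograms.

Workflow for one temperature surface: (1) detrend by subtracting the
ordinary-least-squares plane T = β0 + β1·lat + β2·lon, so the large-scale
gradient does not dominate; (2) bin the squared residual differences of all
point pairs by great-circle lag within an angular window around a chosen
bearing (the empirical directional semivariogram, γ(h) = Σ(z_i − z_j)²/2N);
(3) fit the exponential model γ(h) = c0 + c1·(1 − exp(−h/a)) by weighted
least squares.  The *sill* c0 + c1 is the variance plateau; the
*minimum-distance* d — the lag at which observations become effectively
independent — is taken as the practical range, the lag where the fitted
curve reaches 95 % of the sill (d = a·ln(c1 / (0.05·(c0+c1))), i.e. ≈3a for
a nugget-free model).

Comparing the understory fit against the open-air fit with identical
settings quantifies how much finer-grained the microclimate's spatial
structure is (d_under vs d_open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .grids import Grid, Raster, haversine_km, initial_bearing_deg

DEFAULT_DIRECTION = 90.0       # east-west, the setting used for the headline comparison
DEFAULT_ANGLE_TOL = 22.5       # degrees either side of the direction
DEFAULT_MAX_LAG = 400.0        # km
DEFAULT_BIN_WIDTH = 10.0       # km, one analysis cell


class VariogramFitError(RuntimeError):
    pass


@dataclass
class Semivariogram:
    lag_km: np.ndarray          # bin centres
    gamma: np.ndarray           # semivariance per bin, °C²
    n_pairs: np.ndarray
    direction: float
    tolerance: float
    max_lag: float


@dataclass
class FittedVariogram:
    nugget: float               # c0, °C²
    partial_sill: float         # c1, °C²
    range_param: float          # a, km
    sill: float                 # c0 + c1
    minimum_distance: float | None  # 95 %-of-sill practical range, km; None if undefined
    weighted_sse: float

    def model(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + self.partial_sill * (1.0 - np.exp(-h / self.range_param))


def detrend_surface(lats: np.ndarray, lons: np.ndarray, values: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """OLS plane fit T = β0 + β1·lat + β2·lon; returns (residuals, betas).

    Residuals have exactly zero mean and are orthogonal to lat and lon.
    Degenerate geometry (collinear points) raises a ValueError.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("detrending needs at least 3 points")
    design = np.column_stack([np.ones_like(lats), lats, lons])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate geometry: points are collinear in lat/lon")
    betas, *_ = np.linalg.lstsq(design, values, rcond=None)
    residuals = values - design @ betas
    return residuals, betas


def _pairwise(lats, lons, values, max_points_chunk: int = 4000):
    """Flattened upper-triangle (distance, bearing, half-sq-diff) arrays."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    iu, ju = np.triu_indices(n, k=1)
    d = haversine_km(lats[iu], lons[iu], lats[ju], lons[ju])
    b = initial_bearing_deg(lats[iu], lons[iu], lats[ju], lons[ju])
    sq = 0.5 * (values[iu] - values[ju]) ** 2
    return d, b, sq


def empirical_semivariogram(lats: np.ndarray, lons: np.ndarray, values: np.ndarray,
                            direction: float = DEFAULT_DIRECTION,
                            tolerance: float = DEFAULT_ANGLE_TOL,
                            max_lag: float = DEFAULT_MAX_LAG,
                            bin_width: float = DEFAULT_BIN_WIDTH) -> Semivariogram:
    """Directional empirical semivariogram over scattered points.

    A pair contributes when its great-circle separation is in (0, max_lag]
    and its bearing lies within ``tolerance`` of ``direction`` modulo 180°
    (a variogram direction is an axis, so θ and θ+180° are identical).
    Bins of width ``bin_width`` with zero pairs are omitted.
    """
    if max_lag < bin_width:
        raise ValueError(f"max_lag {max_lag} smaller than one bin ({bin_width})")
    d, b, sq = _pairwise(lats, lons, values)
    ang = np.abs((b - direction + 90.0) % 180.0 - 90.0)   # axial angular distance
    keep = (d > 0) & (d <= max_lag) & (ang <= tolerance)
    d, sq = d[keep], sq[keep]
    edges = np.arange(0.0, max_lag + bin_width, bin_width)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    nbins = len(edges) - 1
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=sq, minlength=nbins)
    nonzero = counts > 0
    centres = (edges[:-1] + edges[1:]) / 2.0
    return Semivariogram(lag_km=centres[nonzero],
                         gamma=sums[nonzero] / counts[nonzero],
                         n_pairs=counts[nonzero],
                         direction=direction, tolerance=tolerance, max_lag=max_lag)


def raster_to_points(raster: Raster) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lats, lons, values) of all valid cells of a raster."""
    lat2d, lon2d = raster.grid.center_mesh()
    m = raster.mask
    return lat2d[m], lon2d[m], raster.values[m]


def coarsen_mean(raster: Raster, factor: int) -> Raster:
    """Block-average a raster by an integer factor (analysis-resolution resample).

    Cells with no valid source cells in their block become no-data.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return Raster(raster.grid, raster.values.copy(), raster.nodata)
    g = raster.grid
    nr, nc = g.nrows // factor, g.ncols // factor
    if nr < 1 or nc < 1:
        raise ValueError("raster smaller than one coarse cell")
    vals = raster.values[:nr * factor, :nc * factor]
    msk = raster.mask[:nr * factor, :nc * factor]
    v = np.where(msk, vals, 0.0).reshape(nr, factor, nc, factor)
    m = msk.reshape(nr, factor, nc, factor)
    counts = m.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, v.sum(axis=(1, 3)) / np.maximum(counts, 1), raster.nodata)
    # coarse grid keeps the same upper-left (north-west) anchor
    coarse = Grid(nrows=nr, ncols=nc,
                  lat_min=g.lat_max - nr * factor * g.cell_size,
                  lon_min=g.lon_min, cell_size=g.cell_size * factor)
    return Raster(coarse, mean, raster.nodata)


def _exp_model(h, c0, c1, a):
    return c0 + c1 * (1.0 - np.exp(-h / a))


def fit_exponential(sv: Semivariogram, weighted: bool = True) -> FittedVariogram:
    """Weighted least-squares fit of the exponential variogram model.

    Weights are the per-bin pair counts.  Parameters are bounded
    non-negative.  The minimum distance is the 95 %-of-sill lag and is
    reported as None when the structured component c1 is too small relative
    to the sill for that lag to exist (pure-nugget case).
    """
    if len(sv.lag_km) < 4:
        raise VariogramFitError(f"need >= 4 bins to fit, got {len(sv.lag_km)}")
    h, g, w = sv.lag_km, sv.gamma, sv.n_pairs.astype(float)
    gmax = float(g.max())
    if gmax == 0:
        return FittedVariogram(0.0, 0.0, float(h.max()), 0.0, None, 0.0)
    c0_0 = max(float(g[0]) - (float(g[1]) - float(g[0])), 0.0)
    p0 = [c0_0, max(gmax - c0_0, 1e-12), max(float(h.max()) / 3.0, sv.max_lag / 20.0)]
    sigma = 1.0 / np.sqrt(w) if weighted else None
    try:
        popt, _ = curve_fit(_exp_model, h, g, p0=p0, sigma=sigma, absolute_sigma=False,
                            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise VariogramFitError(f"exponential variogram fit did not converge: {exc}") from exc
    c0, c1, a = (float(v) for v in popt)
    sill = c0 + c1
    resid = _exp_model(h, c0, c1, a) - g
    wsse = float(np.sum((w if weighted else 1.0) * resid ** 2))
    if sill <= 0 or c1 <= 0.05 * sill:
        d = None                      # flat / pure-nugget: no practical range
    else:
        d = float(a * np.log(c1 / (0.05 * sill)))
    return FittedVariogram(nugget=c0, partial_sill=c1, range_param=a,
                           sill=sill, minimum_distance=d, weighted_sse=wsse)


@dataclass
class HeterogeneityComparison:
    fit_under: FittedVariogram
    fit_open: FittedVariogram
    sv_under: Semivariogram
    sv_open: Semivariogram
    d_ratio: float | None       # d_under / d_open


def analyse_surface(raster: Raster, direction: float = DEFAULT_DIRECTION,
                    tolerance: float = DEFAULT_ANGLE_TOL,
                    max_lag: float = DEFAULT_MAX_LAG,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    coarsen: int = 1) -> tuple[Semivariogram, FittedVariogram]:
    """detrend → directional variogram → exponential fit for one surface."""
    ras = coarsen_mean(raster, coarsen) if coarsen > 1 else raster
    lats, lons, vals = raster_to_points(ras)
    residuals, _ = detrend_surface(lats, lons, vals)
    sv = empirical_semivariogram(lats, lons, residuals, direction=direction,
                                 tolerance=tolerance, max_lag=max_lag, bin_width=bin_width)
    return sv, fit_exponential(sv)


def compare_heterogeneity(t_under: Raster, t_open: Raster,
                          direction: float = DEFAULT_DIRECTION,
                          tolerance: float = DEFAULT_ANGLE_TOL,
                          max_lag: float = DEFAULT_MAX_LAG,
                          bin_width: float = DEFAULT_BIN_WIDTH,
                          coarsen: int = 1) -> HeterogeneityComparison:
    """Run the identical variogram workflow on both surfaces and compare ranges."""
    sv_u, fit_u = analyse_surface(t_under, direction, tolerance, max_lag, bin_width, coarsen)
    sv_o, fit_o = analyse_surface(t_open, direction, tolerance, max_lag, bin_width, coarsen)
    if fit_u.minimum_distance is not None and fit_o.minimum_distance:
        ratio = fit_u.minimum_distance / fit_o.minimum_distance
    else:
        ratio = None
    return HeterogeneityComparison(fit_under=fit_u, fit_open=fit_o,
                                   sv_under=sv_u, sv_open=sv_o, d_ratio=ratio)
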