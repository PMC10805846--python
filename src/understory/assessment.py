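"""Spatial applicability and robustness of the fitted model.

Two diagnostics:

* **Degree of interpolation** — training rows and prediction pixels are
  standardized with the training statistics and projected into a principal
  component space; for every unordered pair of the k retained axes (15 pairs
  when k = 6) a pixel scores 1 if it falls inside the convex hull of the
  training points in that 2-D space and 0 otherwise; the mean over pairs is
  the pixel's degree of interpolation in [0, 1].

* **Buffered spatial leave-one-out CV** — each sensor in turn is held out and
  the model retrained on all sensors farther than a buffer radius; repeating
  with growing radii shows how much apparent accuracy rests on spatial
  autocorrelation between neighbouring sensors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .grids import Raster, haversine_km, DEFAULT_NODATA
from .model import (Hyperparams, fit_bagging, design_matrix, FEATURE_NAMES)
from .synthetic import PredictorStack
from .features import forest_mask, stack_climatology, DEFAULT_TCC_THRESHOLD

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_THRESHOLD = 0.93
HULL_TOL = 1e-9


@dataclass
class PCSpace:
    """Training-data standardization + PCA loadings for the retained axes."""

    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray          # (k, n_features) orthonormal rows
    explained_fractions: np.ndarray  # all axes, non-increasing
    k: int
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    dropped: list[str] = field(default_factory=list)

    def project(self, table: pd.DataFrame) -> np.ndarray:
        """Project rows with the nine logical predictors into the k-D PC space."""
        x = design_matrix(table).to_numpy()
        keep = [i for i, n in enumerate(FEATURE_NAMES) if n not in self.dropped]
        x = x[:, keep]
        z = (x - self.means) / self.sds
        return z @ self.components.T


def fit_pc_space(table: pd.DataFrame,
                 variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD) -> PCSpace:
    """PCA of the standardized training predictors.

    k is the smallest axis count whose cumulative explained variance reaches
    the threshold (at least 2, so bivariate spaces exist).  Zero-variance
    predictors are dropped with a warning.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    x = design_matrix(table).to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 training rows for a PC space")
    sds_all = x.std(axis=0, ddof=0)
    zero_var = sds_all <= 1e-12 * np.maximum(np.abs(x).max(axis=0), 1.0)
    dropped = [FEATURE_NAMES[i] for i in np.nonzero(zero_var)[0]]
    if dropped:
        logger.warning("fit_pc_space: dropping zero-variance predictors: %s", dropped)
    x = x[:, ~zero_var]
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    z = (x - means) / sds
    pca = PCA(n_components=min(z.shape), svd_solver="full")
    pca.fit(z)
    frac = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(frac), variance_threshold - 1e-12) + 1)
    k = max(2, min(k, len(frac)))
    return PCSpace(means=means, sds=sds, components=pca.components_[:k],
                   explained_fractions=frac, k=k, dropped=dropped)


def _hull_halfplanes(points: np.ndarray):
    """Hull facet equations (A, b) with A·p + b <= 0 inside, or None if degenerate."""
    try:
        hull = ConvexHull(points)
    except QhullError:
        return None
    return hull.equations[:, :2], hull.equations[:, 2]


def _segment_membership(points: np.ndarray, queries: np.ndarray, tol: float) -> np.ndarray:
    """Membership against degenerate (collinear / tiny) training sets.

    Points are projected onto the principal direction of the training set;
    a query is inside when it lies within the segment and within ``tol`` of
    the line.
    """
    centre = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - centre, full_matrices=False)
    axis = vt[0]
    t = (points - centre) @ axis
    qt = (queries - centre) @ axis
    perp = (queries - centre) - np.outer(qt, axis)
    on_line = np.linalg.norm(perp, axis=1) <= tol + 1e-12
    return on_line & (qt >= t.min() - tol) & (qt <= t.max() + tol)


def pair_axes(k: int) -> list[tuple[int, int]]:
    """The C(k, 2) unordered axis pairs (15 pairs for k = 6)."""
    return list(itertools.combinations(range(k), 2))


def degree_of_interpolation(space: PCSpace, pixels: pd.DataFrame,
                            table: pd.DataFrame) -> np.ndarray:
    """Mean convex-hull membership over all bivariate PC spaces, per pixel.

    Hull boundaries count as inside (training points score exactly 1).
    Returns an array of values in [0, 1], one per pixel row.
    """
    train = space.project(table)
    pix = space.project(pixels)
    pairs = pair_axes(space.k)
    scores = np.zeros(len(pix))
    for i, j in pairs:
        tp = train[:, [i, j]]
        qp = pix[:, [i, j]]
        scale = max(np.ptp(tp[:, 0]), np.ptp(tp[:, 1]), 1.0)
        hp = _hull_halfplanes(tp) if len(tp) >= 3 else None
        if hp is None:
            logger.info("degree_of_interpolation: degenerate hull in PC pair (%d, %d); "
                        "using bounding-segment membership", i + 1, j + 1)
            inside = _segment_membership(tp, qp, tol=HULL_TOL * scale)
        else:
            a_mat, b = hp
            inside = np.all(qp @ a_mat.T + b <= HULL_TOL * scale, axis=1)
        scores += inside.astype(float)
    return scores / len(pairs)


def interpolation_map(space: PCSpace, stack: PredictorStack, table: pd.DataFrame,
                      month: int, time_scale: str = "daily",
                      tcc_threshold: float = DEFAULT_TCC_THRESHOLD,
                      nodata: float = DEFAULT_NODATA) -> Raster:
    """Degree-of-interpolation raster for one month's composite predictors."""
    mask = forest_mask(stack.tcc, tcc_threshold)
    clim = stack_climatology(stack)[time_scale]
    m = month - 1
    rows, cols = np.nonzero(mask)
    pixels = pd.DataFrame({
        "elevation": stack.elevation[rows, cols],
        "slope": stack.slope[rows, cols],
        "aspect": stack.aspect[rows, cols],
        "lai": stack.lai[rows, cols],
        "fapar": stack.fapar[rows, cols],
        "canopy_height": stack.canopy_height[rows, cols],
        "macro_t": clim[m, rows, cols],
        "macro_precip": stack.macro_precip[m, rows, cols],
        "macro_rad": stack.macro_rad[m, rows, cols],
    })
    values = np.full(stack.grid.shape, nodata, dtype=float)
    if len(pixels):
        values[rows, cols] = degree_of_interpolation(space, pixels, table)
    return Raster(stack.grid, values, nodata=nodata)


def aggregate_interpolation(monthly_maps: list[Raster]) -> Raster:
    """Per-cell mean of monthly interpolation maps (warns when not 12 months)."""
    if not monthly_maps:
        raise ValueError("no monthly maps to aggregate")
    if len(monthly_maps) != 12:
        logger.warning("aggregate_interpolation: %d monthly maps (expected 12); "
                       "averaging the available months", len(monthly_maps))
    first = monthly_maps[0]
    stackv = np.stack([m.values for m in monthly_maps])
    maskv = np.stack([m.mask for m in monthly_maps])
    n = maskv.sum(axis=0)
    total = np.where(maskv, stackv, 0.0).sum(axis=0)
    values = np.where(n > 0, total / np.maximum(n, 1), first.nodata)
    return Raster(first.grid, values, first.nodata)


@dataclass
class BufferedCVResult:
    table: pd.DataFrame             # radius_km, n_eval, rmse, bias, r2, mean_train_size
    stabilization_radius: float | None


def buffered_loocv(table: pd.DataFrame, radii: list[float], hp: Hyperparams,
                   seed: int = 0, stabilization_tol: float = 0.05) -> BufferedCVResult:
    """Spatial leave-one-out CV with growing exclusion buffers.

    For each sensor and each radius, the ensemble is retrained (fixed
    hyperparameters, no re-tuning) on all rows from sensors strictly farther
    than the radius, and the held-out sensor's months are predicted.  Radius
    0 is ordinary leave-one-sensor-out.  Metrics are pooled over sensors per
    radius.  The stabilization radius is the smallest positive radius at
    which RMSE changes by less than ``stabilization_tol`` relative to the
    previous radius, or None if never reached.
    """
    radii = sorted(float(r) for r in radii)
    if not radii or radii[0] != 0.0:
        raise ValueError("radii must be ascending and include 0")
    sensors = table[["sensor_id", "lat", "lon"]].drop_duplicates("sensor_id").reset_index(drop=True)
    if len(sensors) < 2:
        raise ValueError("buffered LOO-CV needs at least 2 sensors")
    dist = haversine_km(sensors["lat"].to_numpy()[:, None], sensors["lon"].to_numpy()[:, None],
                        sensors["lat"].to_numpy()[None, :], sensors["lon"].to_numpy()[None, :])
    rows_by_sensor = {sid: idx.to_numpy() for sid, idx in table.groupby("sensor_id").groups.items()}

    out_rows = []
    for radius in radii:
        preds, obs, train_sizes, n_skipped = [], [], [], 0
        for i, sid in enumerate(sensors["sensor_id"]):
            train_sensors = sensors["sensor_id"][dist[i] > radius]
            train_idx = np.concatenate([rows_by_sensor[s] for s in train_sensors]) if len(train_sensors) else np.array([], dtype=int)
            if len(train_idx) == 0:
                n_skipped += 1
                continue
            ens = fit_bagging(table.loc[train_idx], hp)
            test = table.loc[rows_by_sensor[sid]]
            preds.append(ens.predict(test))
            obs.append(test["response"].to_numpy(dtype=float))
            train_sizes.append(len(train_idx))
        if n_skipped:
            logger.info("buffered_loocv: radius %.0f km left %d sensors with no training data",
                        radius, n_skipped)
        p = np.concatenate(preds)
        o = np.concatenate(obs)
        err = p - o
        sst = float(np.sum((o - o.mean()) ** 2))
        out_rows.append({"radius_km": radius, "n_eval": len(o),
                         "rmse": float(np.sqrt(np.mean(err ** 2))),
                         "bias": float(np.mean(err)),
                         "r2": 1.0 - float(np.sum(err ** 2)) / sst if sst > 0 else np.nan,
                         "mean_train_size": float(np.mean(train_sizes))})
    res = pd.DataFrame(out_rows)
    stab = None
    rmse = res["rmse"].to_numpy()
    for idx in range(1, len(rmse)):
        if abs(rmse[idx] - rmse[idx - 1]) < stabilization_tol * rmse[idx - 1]:
            stab = float(res["radius_km"].iloc[idx])
            break
    return BufferedCVResult(table=res, stabilization_radius=stab)
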