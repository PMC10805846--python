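"""Bagged regression-tree ensemble for understory temperature.

A bootstrap-aggregating (bagging) ensemble of CART regression trees maps the
nine biophysical and macroclimate predictors to a monthly temperature
response.  Each weak learner is fit on a bootstrap resample of the training
rows; at every split a random subset of predictors is considered
(random-forest-style feature subsampling); the ensemble prediction is the
unweighted mean over learners.  Three hyperparameters are tuned by grid
search under 5-fold cross-validation: minimum leaf size (2-8), number of
learners (10-500), and number of predictors sampled (1-8).

One model is trained per temporal scale (daily / day-time / night-time).

The circular ``aspect`` predictor enters design matrices as its sine and
cosine; it still counts as a single logical predictor when mapping the
feature-subsampling hyperparameter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .grids import Raster, DEFAULT_NODATA
from .synthetic import PredictorStack, PREDICTOR_NAMES
from .features import forest_mask, stack_climatology, DEFAULT_TCC_THRESHOLD

#: internal design-matrix columns (aspect expanded to sin/cos)
FEATURE_NAMES = ["elevation", "slope", "aspect_sin", "aspect_cos", "lai", "fapar",
                 "canopy_height", "macro_t", "macro_precip", "macro_rad"]

LEAF_RANGE = (2, 8)
LEARNER_RANGE = (10, 500)
PREDICTOR_RANGE = (1, 8)

DEFAULT_GRID = {
    "min_leaf_size": [2, 4, 6, 8],
    "n_learners": [10, 50, 100, 200, 500],
    "n_predictors_sampled": list(range(1, 9)),
}


@dataclass(frozen=True)
class Hyperparams:
    min_leaf_size: int = 4
    n_learners: int = 100
    n_predictors_sampled: int = 6
    seed: int = 0

    def __post_init__(self):
        if not LEAF_RANGE[0] <= self.min_leaf_size <= LEAF_RANGE[1]:
            raise ValueError(f"min_leaf_size {self.min_leaf_size} outside {LEAF_RANGE}")
        if not LEARNER_RANGE[0] <= self.n_learners <= LEARNER_RANGE[1]:
            raise ValueError(f"n_learners {self.n_learners} outside {LEARNER_RANGE}")
        if not PREDICTOR_RANGE[0] <= self.n_predictors_sampled <= PREDICTOR_RANGE[1]:
            raise ValueError(f"n_predictors_sampled {self.n_predictors_sampled} outside {PREDICTOR_RANGE}")


def design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Expand the nine logical predictors into the internal feature columns."""
    missing = [p for p in PREDICTOR_NAMES if p not in table.columns]
    if missing:
        raise ValueError(f"table is missing predictor columns: {missing}")
    x = pd.DataFrame(index=table.index)
    for name in PREDICTOR_NAMES:
        if name == "aspect":
            rad = np.radians(table["aspect"].to_numpy(dtype=float))
            x["aspect_sin"] = np.sin(rad)
            x["aspect_cos"] = np.cos(rad)
        else:
            x[name] = table[name].to_numpy(dtype=float)
    return x[FEATURE_NAMES]


def _max_features(n_predictors_sampled: int) -> int:
    # map the count over 9 logical predictors onto the 10 internal columns
    return int(np.clip(round(n_predictors_sampled * len(FEATURE_NAMES) / len(PREDICTOR_NAMES)),
                       1, len(FEATURE_NAMES)))


@dataclass
class BaggedEnsemble:
    """A fitted bagging ensemble plus its provenance."""

    model: RandomForestRegressor
    hyperparams: Hyperparams
    predictor_names: list[str] = field(default_factory=lambda: list(PREDICTOR_NAMES))
    n_training_rows: int = 0
    cv_scores: dict | None = None

    @property
    def n_learners(self) -> int:
        return len(self.model.estimators_)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict(design_matrix(table).to_numpy())

    def predict_features(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)


def fit_bagging(table: pd.DataFrame, hp: Hyperparams, bootstrap: bool = True) -> BaggedEnsemble:
    """Fit the bagged-tree ensemble on a training table.

    Each learner sees a bootstrap resample (n rows drawn with replacement);
    ``bootstrap=False`` disables resampling so a single-tree ensemble equals
    that tree (useful for identity checks).  All randomness derives from
    ``hp.seed``.
    """
    if len(table) == 0:
        raise ValueError("empty training table")
    if len(table) < hp.min_leaf_size:
        raise ValueError(f"{len(table)} rows < min_leaf_size {hp.min_leaf_size}")
    x = design_matrix(table).to_numpy()
    y = table["response"].to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("training table contains missing values")
    rf = RandomForestRegressor(
        n_estimators=hp.n_learners,
        min_samples_leaf=hp.min_leaf_size,
        max_features=_max_features(hp.n_predictors_sampled),
        bootstrap=bootstrap,
        random_state=hp.seed,
        n_jobs=1,
    )
    rf.fit(x, y)
    return BaggedEnsemble(model=rf, hyperparams=hp, n_training_rows=len(table))


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def cross_validate(table: pd.DataFrame, hp: Hyperparams, k: int = 5,
                   seed: int = 0) -> dict:
    """K-fold CV of one hyperparameter point; returns rmse/r2 summaries."""
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    y = table["response"].to_numpy(dtype=float)
    preds = np.full(len(table), np.nan)
    rmses = []
    for train_idx, test_idx in folds.split(table):
        ens = fit_bagging(table.iloc[train_idx], hp)
        p = ens.predict(table.iloc[test_idx])
        preds[test_idx] = p
        rmses.append(_rmse(p, y[test_idx]))
    sse = float(np.sum((preds - y) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return {"rmse_mean": float(np.mean(rmses)), "rmse_folds": rmses,
            "r2": 1.0 - sse / sst if sst > 0 else np.nan,
            "rmse_pooled": _rmse(preds, y)}


def grid_search_cv(table: pd.DataFrame, grid: list[Hyperparams] | None = None,
                   k: int = 5, seed: int = 0) -> tuple[Hyperparams, pd.DataFrame]:
    """Grid-search hyperparameters under a shared seed-determined k-fold split.

    The same fold partition is reused at every grid point; the best point has
    the lowest mean CV RMSE (first wins on exact ties).  Returns it together
    with the full per-point report.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} training rows")
    if grid is None:
        grid = default_grid(seed)
    report_rows = []
    best_hp, best_rmse = None, np.inf
    for hp in grid:
        res = cross_validate(table, hp, k=k, seed=seed)
        report_rows.append({"min_leaf_size": hp.min_leaf_size,
                            "n_learners": hp.n_learners,
                            "n_predictors_sampled": hp.n_predictors_sampled,
                            "cv_rmse": res["rmse_mean"], "cv_r2": res["r2"]})
        if res["rmse_mean"] < best_rmse:
            best_rmse, best_hp = res["rmse_mean"], hp
    return best_hp, pd.DataFrame(report_rows)


def default_grid(seed: int = 0) -> list[Hyperparams]:
    """The default grid lattice over the three tunable hyperparameters."""
    return [Hyperparams(a, b, c, seed=seed)
            for a, b, c in itertools.product(DEFAULT_GRID["min_leaf_size"],
                                             DEFAULT_GRID["n_learners"],
                                             DEFAULT_GRID["n_predictors_sampled"])]


def predict_raster(ensemble: BaggedEnsemble, stack: PredictorStack, month: int,
                   time_scale: str = "daily",
                   tcc_threshold: float = DEFAULT_TCC_THRESHOLD,
                   nodata: float = DEFAULT_NODATA) -> Raster:
    """Predict the understory temperature surface for one month.

    Only forest-masked cells are predicted; all other cells carry ``nodata``.
    Output georeferencing equals the stack's grid.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month {month} outside 1-12")
    mask = forest_mask(stack.tcc, tcc_threshold)
    clim = stack_climatology(stack)[time_scale]
    m = month - 1
    rows, cols = np.nonzero(mask)
    table = pd.DataFrame({
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
    if len(table):
        values[rows, cols] = ensemble.predict(table)
    return Raster(stack.grid, values, nodata=nodata)


def variable_importance(ensemble: BaggedEnsemble, table: pd.DataFrame,
                        seed: int = 0, n_repeats: int = 5) -> pd.Series:
    """Permutation importance: RMSE increase when one predictor is shuffled.

    The two aspect components are permuted jointly (one logical predictor).
    Raw differences are reported — small negative values are possible and are
    not floored at zero.
    """
    rng = np.random.default_rng(seed)
    x = design_matrix(table).to_numpy()
    y = table["response"].to_numpy(dtype=float)
    base = _rmse(ensemble.predict_features(x), y)
    groups = {name: ([FEATURE_NAMES.index("aspect_sin"), FEATURE_NAMES.index("aspect_cos")]
                     if name == "aspect" else [FEATURE_NAMES.index(name)])
              for name in PREDICTOR_NAMES}
    out = {}
    for name, cols in groups.items():
        deltas = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(y))
            xp = x.copy()
            xp[:, cols] = x[perm][:, cols]
            deltas.append(_rmse(ensemble.predict_features(xp), y) - base)
        out[name] = float(np.mean(deltas))
    return pd.Series(out, name="rmse_increase")


def partial_dependence(ensemble: BaggedEnsemble, table: pd.DataFrame,
                       predictor: str, grid_values: np.ndarray) -> pd.DataFrame:
    """Mean prediction with one predictor clamped to each grid value."""
    if predictor not in PREDICTOR_NAMES:
        raise ValueError(f"unknown predictor {predictor!r}")
    curve = []
    work = table.copy()
    for v in np.asarray(grid_values, dtype=float):
        work[predictor] = v
        curve.append(float(np.mean(ensemble.predict(work))))
    return pd.DataFrame({predictor: np.asarray(grid_values, dtype=float), "mean_prediction": curve})
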