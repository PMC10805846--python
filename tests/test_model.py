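"""Bagged-tree ensemble: fitting, CV model selection, raster prediction,
importance and partial dependence."""

import numpy as np
import pandas as pd
import pytest

import understory as u
from understory.model import (Hyperparams, fit_bagging, cross_validate,
                              grid_search_cv, predict_raster,
                              variable_importance, partial_dependence,
                              design_matrix, FEATURE_NAMES)
from understory.synthetic import PREDICTOR_NAMES
from understory.features import forest_mask, stack_climatology


def _random_table(n, seed, response_fn=None):
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame({
        "elevation": rng.uniform(0, 1500, n),
        "slope": rng.uniform(0, 45, n),
        "aspect": rng.uniform(0, 360, n),
        "lai": rng.uniform(0, 7, n),
        "fapar": rng.uniform(0, 1, n),
        "canopy_height": rng.uniform(2, 40, n),
        "macro_t": rng.uniform(18, 30, n),
        "macro_precip": rng.uniform(0, 400, n),
        "macro_rad": rng.uniform(5e6, 2.5e7, n),
    })
    tab["sensor_id"] = [f"S{i}" for i in range(n)]
    tab["lat"] = rng.uniform(-5, 5, n)
    tab["lon"] = rng.uniform(20, 30, n)
    if response_fn is None:
        response_fn = lambda t: t["macro_t"] - 6.5 * t["elevation"] / 1000.0
    tab["response"] = response_fn(tab)
    return tab


class TestHyperparams:
    @pytest.mark.parametrize("kw", [{"min_leaf_size": 1}, {"min_leaf_size": 9},
                                    {"n_learners": 5}, {"n_learners": 501},
                                    {"n_predictors_sampled": 0},
                                    {"n_predictors_sampled": 9}])
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(ValueError):
            Hyperparams(**kw)

    def test_aspect_expanded_in_design_matrix(self):
        tab = _random_table(10, 0)
        x = design_matrix(tab)
        assert list(x.columns) == FEATURE_NAMES
        np.testing.assert_allclose(x["aspect_sin"] ** 2 + x["aspect_cos"] ** 2, 1.0)


class TestFitBagging:
    def test_single_tree_without_bootstrap_is_identity(self):
        tab = _random_table(60, 1)
        hp = Hyperparams(min_leaf_size=2, n_learners=10, n_predictors_sampled=8, seed=0)
        ens = fit_bagging(tab, hp, bootstrap=False)
        tree_preds = np.mean([t.predict(design_matrix(tab).to_numpy())
                              for t in ens.model.estimators_], axis=0)
        np.testing.assert_allclose(ens.predict(tab), tree_preds)

    def test_constant_response_predicts_constant(self):
        tab = _random_table(40, 2, response_fn=lambda t: np.full(len(t), 7.0))
        ens = fit_bagging(tab, Hyperparams(seed=0))
        np.testing.assert_allclose(ens.predict(tab), 7.0)

    def test_ensemble_size_and_mean_aggregation(self):
        tab = _random_table(50, 3)
        hp = Hyperparams(n_learners=20, seed=1)
        ens = fit_bagging(tab, hp)
        assert ens.n_learners == 20
        x = design_matrix(tab).to_numpy()
        per_tree = np.mean([t.predict(x) for t in ens.model.estimators_], axis=0)
        np.testing.assert_allclose(ens.predict(tab), per_tree, rtol=1e-12)

    def test_fixed_seed_bit_identical(self):
        tab = _random_table(50, 4)
        hp = Hyperparams(seed=5)
        a = fit_bagging(tab, hp).predict(tab)
        b = fit_bagging(tab, hp).predict(tab)
        np.testing.assert_array_equal(a, b)

    def test_too_few_rows_rejected(self):
        tab = _random_table(3, 5)
        with pytest.raises(ValueError):
            fit_bagging(tab, Hyperparams(min_leaf_size=8))

    def test_noiseless_training_r2(self, noiseless_table):
        hp = Hyperparams(min_leaf_size=2, n_learners=200, n_predictors_sampled=6, seed=0)
        ens = fit_bagging(noiseless_table, hp)
        y = noiseless_table["response"].to_numpy()
        pred = ens.predict(noiseless_table)
        r2 = 1 - np.sum((pred - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 >= 0.99

    def test_seed_variance_shrinks_with_ensemble_size(self):
        tab = _random_table(80, 6)
        probe = _random_table(20, 7)

        def spread(n_learners):
            preds = [fit_bagging(tab, Hyperparams(n_learners=n_learners, seed=s)).predict(probe)
                     for s in range(6)]
            return np.var(np.stack(preds), axis=0).mean()

        assert spread(200) < spread(10)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        tab = _random_table(40, 8)
        hp = Hyperparams(n_learners=10, seed=0)
        best, report = grid_search_cv(tab, [hp], k=4, seed=0)
        assert best == hp and len(report) == 1

    def test_duplicate_points_identical_scores(self):
        tab = _random_table(40, 9)
        hp = Hyperparams(n_learners=10, seed=0)
        _, report = grid_search_cv(tab, [hp, hp], k=4, seed=0)
        assert report["cv_rmse"].iloc[0] == report["cv_rmse"].iloc[1]

    def test_k_exceeding_rows_rejected(self):
        tab = _random_table(4, 10)
        with pytest.raises(ValueError):
            grid_search_cv(tab, [Hyperparams(n_learners=10)], k=10)

    def test_selects_lower_rmse_point(self, noiseless_table):
        coarse = Hyperparams(min_leaf_size=8, n_learners=10, n_predictors_sampled=1, seed=0)
        fine = Hyperparams(min_leaf_size=2, n_learners=100, n_predictors_sampled=6, seed=0)
        best, report = grid_search_cv(noiseless_table, [coarse, fine], k=5, seed=0)
        assert best == fine


class TestPredictRaster:
    def test_masked_cells_get_nodata_and_georef_preserved(self, stack, noiseless_table):
        ens = fit_bagging(noiseless_table, Hyperparams(n_learners=10, seed=0))
        ras = predict_raster(ens, stack, month=1)
        mask = forest_mask(stack.tcc)
        assert ras.grid == stack.grid
        assert np.all(ras.values[~mask] == ras.nodata)
        assert ras.mask.sum() == mask.sum()

    def test_equal_cells_equal_predictions(self, uniform_stack):
        # all predictors constant -> all predictions equal
        uniform_stack.elevation[:] = 500.0
        tab = _random_table(40, 11)
        ens = fit_bagging(tab, Hyperparams(n_learners=10, seed=0))
        ras = predict_raster(ens, uniform_stack, month=1)
        vals = ras.valid_values()
        assert np.all(vals == vals[0])

    def test_noiseless_world_heldout_mae(self, stack, noiseless_table):
        # recover the monthly truth surface to within 0.5 °C on non-sensor cells
        hp = Hyperparams(min_leaf_size=2, n_learners=200, n_predictors_sampled=6, seed=0)
        ens = fit_bagging(noiseless_table, hp)
        ras = predict_raster(ens, stack, month=2)
        params = u.GenerativeParams(noise_sd=0.0, spatial_sill=0.0, seed=13)
        clim = stack_climatology(stack)["daily"][1]
        truth = (clim + params.base_offset + params.lapse_rate * stack.elevation / 1000.0
                 + 0.5 * params.night_warming * stack.fapar)
        mask = forest_mask(stack.tcc)
        sensor_cells = {stack.grid.index_of(la, lo)
                        for la, lo in zip(noiseless_table["lat"], noiseless_table["lon"])}
        held = mask.copy()
        for r, c in sensor_cells:
            held[r, c] = False
        mae = np.abs(ras.values - truth)[held].mean()
        assert mae <= 0.5


class TestImportanceAndPartialDependence:
    def test_irrelevant_predictor_near_zero_importance(self):
        tab = _random_table(300, 12)  # response ignores slope entirely
        ens = fit_bagging(tab, Hyperparams(min_leaf_size=2, n_learners=100,
                                           n_predictors_sampled=6, seed=0))
        imp = variable_importance(ens, tab, seed=0)
        assert abs(imp["slope"]) < 0.15 * imp.max()

    def test_dominant_predictor_ranked_first(self):
        for seed in range(5):
            tab = _random_table(300, 100 + seed,
                                response_fn=lambda t: -6.5 * t["elevation"] / 1000.0
                                + 0.05 * t["lai"])
            ens = fit_bagging(tab, Hyperparams(min_leaf_size=2, n_learners=100,
                                               n_predictors_sampled=6, seed=seed))
            imp = variable_importance(ens, tab, seed=seed)
            assert imp.idxmax() == "elevation"

    def test_identity_permutation_zero_increase(self):
        # permuting a column with itself cannot change RMSE: verified by
        # permuting a constant column
        tab = _random_table(100, 13)
        tab["slope"] = 10.0
        ens = fit_bagging(tab, Hyperparams(n_learners=20, seed=0))
        imp = variable_importance(ens, tab, seed=0)
        assert imp["slope"] == 0.0

    def test_flat_curve_for_constant_ensemble(self):
        tab = _random_table(40, 14, response_fn=lambda t: np.full(len(t), 5.0))
        ens = fit_bagging(tab, Hyperparams(n_learners=10, seed=0))
        curve = partial_dependence(ens, tab, "elevation", np.linspace(0, 1500, 8))
        assert curve["mean_prediction"].nunique() == 1

    def test_monotone_decreasing_elevation_dependence(self):
        tab = _random_table(400, 15, response_fn=lambda t: -6.5 * t["elevation"] / 1000.0)
        ens = fit_bagging(tab, Hyperparams(min_leaf_size=2, n_learners=100,
                                           n_predictors_sampled=8, seed=0))
        curve = partial_dependence(ens, tab, "elevation", np.linspace(50, 1450, 12))
        diffs = np.diff(curve["mean_prediction"])
        assert curve["mean_prediction"].iloc[-1] < curve["mean_prediction"].iloc[0]
        assert np.all(diffs <= 0.05)  # tree plateaus allowed, no real increases

    def test_clamped_definition_matches_rowwise(self):
        tab = _random_table(30, 16)
        ens = fit_bagging(tab, Hyperparams(n_learners=10, seed=0))
        v = float(tab["lai"].iloc[0])
        curve = partial_dependence(ens, tab, "lai", [v])
        rowwise = []
        for i in range(len(tab)):
            row = tab.iloc[[i]].copy()
            row["lai"] = v
            rowwise.append(ens.predict(row)[0])
        assert curve["mean_prediction"].iloc[0] == pytest.approx(np.mean(rowwise), abs=1e-12)
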