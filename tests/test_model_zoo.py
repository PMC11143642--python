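"""Tests for the surrogate families, hyperparameter spaces, and stacking."""

import numpy as np
import pytest

from culturopt import (
    BASE_KINDS, SPACES, StandardizationParams, fit, fit_stacking, predict,
)
from culturopt.model_zoo import DOSE_BOUNDS
from culturopt.tune import make_positional_folds

RNG = np.random.default_rng(0)

XGB_FAST = {"n_estimators": 50, "learning_rate": 0.1, "gamma": 0.0,
            "max_depth": 4, "subsample": 1.0, "colsample_bytree": 1.0,
            "min_child_weight": 1.0, "reg_lambda": 1.0, "reg_alpha": 0.0}
SVR_DEFAULT = {"gamma": 1.0, "C": 10.0, "epsilon": 0.1}
ENMLR_SMALL = {"alpha": 0.01, "l1_ratio": 0.5}
# deep trees over duplicated distinct points: with every distinct point
# near-surely in each bootstrap sample, the forest memorizes the mapping
RF_MEMORIZE = {"n_estimators": 10, "max_features": 1.0, "max_depth": 50,
               "min_samples_split": 2, "min_samples_leaf": 1,
               "min_weight_fraction_leaf": 0.0, "max_leaf_nodes": 200}


def toy_problem(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.5, 1.5, size=(n, 2))
    y = 2.0 + X[:, 0] - 0.5 * X[:, 1] ** 2 + 0.05 * rng.normal(size=n)
    return X, y


class TestHyperparameterSpaces:
    @pytest.mark.parametrize("kind", list(SPACES))
    def test_random_samples_always_valid(self, kind):
        space = SPACES[kind]
        rng = np.random.default_rng(42)
        for _ in range(200):
            space.validate(space.sample(rng))

    def test_boundary_values_accepted(self):
        hp = dict(XGB_FAST, n_estimators=1500, learning_rate=0.001, gamma=10.0)
        SPACES["XGB"].validate(hp)
        SPACES["SVR"].validate({"gamma": 10.0, "C": 50.0, "epsilon": 5.0})

    def test_out_of_bounds_rejected_naming_dimension(self):
        with pytest.raises(ValueError, match="n_estimators"):
            SPACES["XGB"].validate(dict(XGB_FAST, n_estimators=2000))
        with pytest.raises(ValueError, match="gamma"):
            SPACES["SVR"].validate({"gamma": 0.0, "C": 1.0, "epsilon": 0.1})
        with pytest.raises(ValueError, match="l1_ratio"):
            SPACES["ENMLR"].validate({"alpha": 1.0, "l1_ratio": 1.2})

    def test_integer_dimension_rejects_fractional(self):
        with pytest.raises(ValueError, match="max_depth"):
            SPACES["XGB"].validate(dict(XGB_FAST, max_depth=3.5))


class TestStandaloneFits:
    def test_enmlr_unpenalized_recovers_linear_data(self):
        X = RNG.normal(size=(30, 2))
        y = 2.0 * X[:, 0] + 1.0
        m = fit("ENMLR", {"alpha": 0.0, "l1_ratio": 0.5}, X, y)
        assert np.allclose(m.predict_standardized(X), y, atol=1e-6)

    def test_deep_rf_memorizes_distinct_points(self):
        base_X = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        base_y = np.array([1.0, 3.0, -2.0, 7.0, 0.5])
        X, y = np.tile(base_X, (12, 1)), np.tile(base_y, 12)
        m = fit("RF", RF_MEMORIZE, X, y, seed=0)
        assert np.allclose(m.predict_standardized(base_X), base_y, atol=1e-9)

    def test_svr_constant_target_within_epsilon(self):
        X = np.array([[0.0, 0], [1, 1], [2, 0]])
        y = np.array([5.0, 5.0, 5.0])
        m = fit("SVR", SVR_DEFAULT, X, y)
        # constant target has zero spread; internal target scaling is a no-op
        assert np.all(np.abs(m.predict_standardized(X) - 5.0) <= SVR_DEFAULT["epsilon"])

    def test_fit_rejects_out_of_space_hyperparams(self):
        X, y = toy_problem()
        with pytest.raises(ValueError, match="C"):
            fit("SVR", {"gamma": 1.0, "C": 100.0, "epsilon": 0.1}, X, y)

    @pytest.mark.parametrize("kind,hp", [
        ("XGB", XGB_FAST), ("RF", RF_MEMORIZE), ("SVR", SVR_DEFAULT),
        ("ENMLR", ENMLR_SMALL),
    ])
    def test_refit_reproducibility(self, kind, hp):
        X, y = toy_problem()
        probe = np.linspace(-1, 1, 11)[:, None] * np.ones((1, 2))
        a = fit(kind, hp, X, y, seed=3).predict_standardized(probe)
        b = fit(kind, hp, X, y, seed=3).predict_standardized(probe)
        assert np.allclose(a, b, atol=1e-9)


class TestPredictContract:
    @pytest.fixture()
    def es_model(self, full_table):
        sub = full_table[full_table.cultivar == "Atabaki"].reset_index(drop=True)
        params = StandardizationParams(mu=np.array([0.2125, 0.375]),
                                       sigma=np.array([0.19, 0.28]))
        from culturopt.preprocess import FEATURES, standardize

        Z = standardize(sub[FEATURES].to_numpy(float), params)
        return fit("XGB", XGB_FAST, Z, sub["ES_pct"].to_numpy(float),
                   standardizer=params, trait="ES", cultivar="Atabaki")

    def test_identical_doses_identical_predictions(self, es_model):
        p = predict(es_model, [[0.25, 0.5], [0.25, 0.5]])
        assert p[0] == p[1]

    def test_out_of_bounds_dose_rejected(self, es_model):
        with pytest.raises(ValueError, match="bounds"):
            predict(es_model, [[0.6, 0.5]])
        # allowed when extrapolation is explicit
        predict(es_model, [[0.6, 0.5]], extrapolate=True)

    def test_es_predictions_clipped_on_dose_grid(self, es_model):
        g = np.linspace(*DOSE_BOUNDS["ga3"], 21)
        z = np.linspace(*DOSE_BOUNDS["zt"], 21)
        grid = np.array([(a, b) for a in g for b in z])
        p = predict(es_model, grid)
        assert np.all((p >= 0) & (p <= 100))

    def test_memorizing_rf_predicts_training_target(self):
        params = StandardizationParams(mu=np.zeros(2), sigma=np.ones(2))
        base_X = np.array([[0.0, 0], [0.1, 0.25], [0.25, 0.5], [0.5, 0.75],
                           [0.3, 0.1]])
        base_y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X, y = np.tile(base_X, (12, 1)), np.tile(base_y, 12)
        m = fit("RF", RF_MEMORIZE, X, y, standardizer=params, trait="LN")
        assert predict(m, [[0.25, 0.5]])[0] == pytest.approx(3.0)


class TestPersistence:
    def test_manifest_and_blob_round_trip(self, tmp_path):
        from culturopt.model_zoo import load_model, save_model

        X, y = toy_problem()
        params = StandardizationParams(mu=np.zeros(2), sigma=np.ones(2))
        m = fit("ENMLR", ENMLR_SMALL, X, y, seed=2, standardizer=params,
                trait="SL", cultivar="Atabaki")
        save_model(m, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        probe = np.linspace(-1, 1, 7)[:, None] * np.ones((1, 2))
        assert np.allclose(loaded.predict_standardized(probe),
                           m.predict_standardized(probe))
        import json

        manifest = json.loads((tmp_path / "model.json").read_text())
        assert manifest["model_kind"] == "ENMLR"
        assert manifest["trait"] == "SL"


class TestStacking:
    @pytest.fixture()
    def base_params(self):
        return {"XGB": XGB_FAST, "SVR": SVR_DEFAULT, "ENMLR": ENMLR_SMALL}

    def test_meta_feature_shape_contract(self, base_params):
        X, y = toy_problem(n=50)
        folds = make_positional_folds(50, 5, seed=1)
        m = fit_stacking(X, y, folds, base_params, seed=0)
        oof = m.extras["oof_features"]
        assert oof.shape == (50, 3)
        assert np.all(np.isfinite(oof))

    def test_leakage_guard_oof_columns(self, base_params):
        """Each out-of-fold entry equals the prediction of a base refitted
        without that row's fold (recomputed independently here)."""
        X, y = toy_problem(n=30)
        folds = make_positional_folds(30, 3, seed=2)
        m = fit_stacking(X, y, folds, base_params, seed=5)
        oof, oof_fold = m.extras["oof_features"], m.extras["oof_fold"]
        for k, val_idx in enumerate(folds):
            assert np.all(oof_fold[val_idx] == k)
            fit_idx = np.setdiff1d(np.arange(30), val_idx)
            for j, kind in enumerate(BASE_KINDS):
                ref = fit(kind, base_params[kind], X[fit_idx], y[fit_idx], seed=5)
                assert np.allclose(oof[val_idx, j],
                                   ref.predict_standardized(X[val_idx]), atol=1e-9)

    def test_consensus_on_constant_target(self, base_params):
        X = RNG.normal(size=(40, 2))
        y = np.full(40, 3.25)
        folds = make_positional_folds(40, 4, seed=0)
        m = fit_stacking(X, y, folds, base_params, seed=0)
        pred = m.predict_standardized(RNG.normal(size=(10, 2)))
        assert np.allclose(pred, 3.25, atol=SVR_DEFAULT["epsilon"] + 1e-6)

    def test_invalid_folds_rejected(self, base_params):
        X, y = toy_problem(n=20)
        folds = make_positional_folds(20, 4, seed=0)[:-1]  # drop one fold
        with pytest.raises(ValueError, match="partition"):
            fit_stacking(X, y, folds, base_params)

    def test_failing_base_named(self, base_params):
        X, y = toy_problem(n=20)
        folds = make_positional_folds(20, 4, seed=0)
        bad = dict(base_params, SVR={"gamma": -1.0, "C": 1.0, "epsilon": 0.1})
        with pytest.raises((RuntimeError, ValueError), match="SVR"):
            fit_stacking(X, y, folds, bad)

    def test_esr_not_worse_than_worst_base(self, base_params):
        """Stacked test RMSE <= max base test RMSE in a majority of seeds."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-1.5, 1.5, size=(160, 2))
            y = 3 + np.sin(2 * X[:, 0]) + 0.3 * X[:, 1] + 0.2 * rng.normal(size=160)
            tr, te = np.arange(120), np.arange(120, 160)
            folds = make_positional_folds(120, 5, seed=seed)
            esr = fit_stacking(X[tr], y[tr], folds, base_params, seed=seed)
            esr_rmse = np.sqrt(np.mean((y[te] - esr.predict_standardized(X[te])) ** 2))
            base_rmse = max(
                np.sqrt(np.mean((y[te] - fit(k, base_params[k], X[tr], y[tr],
                                             seed=seed).predict_standardized(X[te])) ** 2))
                for k in BASE_KINDS
            )
            wins += esr_rmse <= base_rmse
        assert wins >= 6
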