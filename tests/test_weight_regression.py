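"""BP network forward/training, the published hidden layer, and the
five-model comparison harness."""

import numpy as np
import pandas as pd
import pytest

from cowseg.synthetic_scenes import SceneParams, generate_feature_table
from cowseg.weight_regression import (
    BPNetParams,
    BPRegressor,
    bp_forward,
    bp_hidden_preactivation,
    compare_models,
    fit_gpr,
    fit_mlr,
    fit_svr,
    fit_tree,
    load_published_hidden_layer,
    train_bp_lm,
)

PUBLISHED_BIASES = [2.2288, 1.9718, -1.1727, 0.4229, -0.0952,
                    0.4524, -0.0802, -1.1329, -2.2368, 2.0389]


class TestPublishedHiddenLayer:
    def test_structure(self):
        p = load_published_hidden_layer()
        assert p.n_hidden == 10
        assert p.n_features == 5
        assert not p.output_layer_known

    def test_zero_input_reproduces_biases(self):
        p = load_published_hidden_layer()
        pre = bp_hidden_preactivation(p, np.zeros(5))[0]
        np.testing.assert_allclose(pre, PUBLISHED_BIASES, atol=1e-12)

    def test_column_permutation(self):
        # canonical order is (A_t, A_b, H_t, H_b, age); age is column 4
        p = load_published_hidden_layer()
        assert p.W1[3, 4] == pytest.approx(1.4218)   # neuron 4, age weight
        assert p.W1[0, 2] == pytest.approx(1.7498)   # neuron 1, H_t weight

    def test_prediction_without_output_layer_flagged_absent(self):
        p = load_published_hidden_layer()
        y, pre = bp_forward(p, np.zeros(5))
        assert y is None
        assert pre.shape == (1, 10)


class TestBPForward:
    def test_zero_hidden_weights_output_is_bias(self, rng):
        p = BPNetParams(W1=rng.normal(0, 1, (10, 5)), b1=rng.normal(0, 1, 10),
                        W2=np.zeros((1, 10)), b2=np.array([3.5]))
        y, _ = bp_forward(p, rng.normal(0, 1, (7, 5)))
        np.testing.assert_allclose(y, 3.5)

    def test_single_unit_hand_evaluation(self):
        p = BPNetParams(W1=np.array([[1.0, 0, 0, 0, 0]]), b1=np.zeros(1),
                        W2=np.array([[1.0]]), b2=np.zeros(1))
        y, pre = bp_forward(p, np.array([0.5, 0.1, 0.2, 0.3, 0.4]))
        assert pre[0, 0] == pytest.approx(0.5)
        assert y[0] == pytest.approx(np.tanh(0.5), abs=1e-12)
        assert y[0] == pytest.approx(0.4621, abs=1e-4)

    def test_shape_validation(self):
        p = BPNetParams(W1=np.zeros((10, 5)), b1=np.zeros(10),
                        W2=np.zeros((1, 10)), b2=np.zeros(1))
        with pytest.raises(ValueError):
            bp_forward(p, np.zeros(4))


class TestTrainBPLM:
    def test_zero_epochs_returns_initialization(self, rng):
        X = rng.normal(0, 1, (30, 5))
        y = rng.normal(0, 1, 30)
        p1 = train_bp_lm(X, y, seed=3, max_epochs=0)
        p2 = train_bp_lm(X, y, seed=3, max_epochs=0)
        np.testing.assert_array_equal(p1.W1, p2.W1)

    def test_matches_ols_on_noiseless_linear_data(self, rng):
        X = rng.uniform(-1, 1, (200, 5))
        y = 2 * X[:, 0] - X[:, 2] + 0.5
        Xte = rng.uniform(-1, 1, (100, 5))
        mlr = fit_mlr(X, y)
        p = train_bp_lm(X, y, n_hidden=10, seed=1, max_epochs=200)
        yhat, _ = bp_forward(p, Xte)
        rmse = np.sqrt(np.mean((yhat - mlr.predict(Xte)) ** 2))
        assert rmse < 1e-3

    def test_sse_non_increasing_over_training(self, rng):
        X = rng.uniform(-1, 1, (80, 5))
        y = np.sin(2 * X[:, 0]) + 0.3 * X[:, 1]

        def sse(params):
            yh, _ = bp_forward(params, X)
            return float(np.sum((yh - y) ** 2))

        prev = sse(train_bp_lm(X, y, seed=0, max_epochs=0))
        for epochs in (5, 20, 80):
            cur = sse(train_bp_lm(X, y, seed=0, max_epochs=epochs))
            assert cur <= prev + 1e-9
            prev = cur

    def test_seeded_determinism(self, rng):
        X = rng.uniform(-1, 1, (60, 5))
        y = X @ np.array([1.0, -0.5, 0.2, 0, 0.7])
        p1 = train_bp_lm(X, y, seed=5, max_epochs=30)
        p2 = train_bp_lm(X, y, seed=5, max_epochs=30)
        np.testing.assert_array_equal(p1.W1, p2.W1)
        np.testing.assert_array_equal(p1.W2, p2.W2)

    def test_underdetermined_fit_warns(self, rng):
        with pytest.warns(UserWarning, match="samples"):
            train_bp_lm(rng.normal(0, 1, (10, 5)), rng.normal(0, 1, 10),
                        max_epochs=2)


class TestClassicalModels:
    def test_mlr_recovers_coefficients_exactly(self, rng):
        beta = np.array([2.0, -1.0, 0.5, 3.0, -0.25])
        X = rng.normal(0, 1, (50, 5))
        y = 7.0 + X @ beta
        m = fit_mlr(X, y)
        assert m.intercept == pytest.approx(7.0, abs=1e-8)
        np.testing.assert_allclose(m.coef, beta, atol=1e-8)

    def test_tree_without_usable_split_predicts_target_mean(self, rng):
        # constant features leave the root unsplit: a depth-limited tree
        # degenerates to the target mean everywhere
        X = np.ones((40, 5))
        y = rng.normal(100, 10, 40)
        m = fit_tree(X, y, max_depth=3, seed=0)
        np.testing.assert_allclose(m.predict(X), y.mean())

    def test_gpr_interpolates_as_noise_vanishes(self, rng):
        X = rng.uniform(-1, 1, (25, 5))
        y = X @ np.array([1.0, 0.5, 0, 0, -1.0])
        m = fit_gpr(X, y, seed=0)
        pred = m.predict(X)
        assert np.abs(pred - y).max() < 0.1

    def test_svr_fits_smooth_function(self, rng):
        X = rng.uniform(-1, 1, (150, 5))
        y = 100 + 50 * X[:, 0] + 20 * np.sin(2 * X[:, 1])
        m = fit_svr(X, y)
        rmse = np.sqrt(np.mean((m.predict(X) - y) ** 2))
        assert rmse < 10.0


class TestBPRegressor:
    def test_recovery_on_generator_data(self):
        df = generate_feature_table(SceneParams(seed=8), 600, seed=8)
        X = df[["A_t", "A_b", "H_t", "H_b", "age"]].to_numpy()
        y = df["weight"].to_numpy()
        reg = BPRegressor(seed=8).fit(X[:500], y[:500])
        pred = reg.predict(X[500:])
        resid = y[500:] - pred
        r2 = 1 - resid.var() / y[500:].var()
        assert r2 > 0.95


    def test_constant_feature_column_tolerated(self, rng):
        X = rng.uniform(-1, 1, (60, 5))
        X[:, 0] = 0.0  # e.g. empty predicted masks -> all-zero areas
        y = 300 + 50 * X[:, 2]
        with pytest.warns(UserWarning, match="no information"):
            reg = BPRegressor(seed=0, max_epochs=50).fit(X, y)
        assert np.isfinite(reg.predict(X)).all()


class TestCompareModels:
    @pytest.fixture(scope="class")
    def tables(self):
        df = generate_feature_table(SceneParams(seed=2), 120, seed=2)
        return df.iloc[:100], df.iloc[100:]

    def test_output_structure(self, tables):
        train, test = tables
        table, scatter = compare_models(train, test, seed=2)
        assert len(table) == 5 * 2
        assert set(table["model"]) == {"MLR", "DT", "SVM", "GR", "BP"}
        assert set(table["split"]) == {"train", "test"}
        assert {"R2", "RMSE", "MSE", "MAE"} <= set(table.columns)
        assert set(scatter) == {"MLR", "DT", "SVM", "GR", "BP"}

    def test_train_equals_test_when_same_split(self, tables):
        train, _ = tables
        table, _ = compare_models(train, train, models=("MLR",), seed=0)
        tr = table[table.split == "train"].iloc[0]
        te = table[table.split == "test"].iloc[0]
        assert tr["RMSE"] == pytest.approx(te["RMSE"])
        assert tr["R2"] == pytest.approx(te["R2"])

    def test_failing_model_recorded_not_fatal(self, tables):
        train, test = tables
        with pytest.warns(UserWarning, match="failed"):
            table, _ = compare_models(train, test, models=("MLR", "bogus"), seed=0)
        # typo-like tag is recorded with NaN metrics, MLR still present
        assert np.isnan(table[table.model == "bogus"]["RMSE"]).all()
        assert np.isfinite(table[table.model == "MLR"]["RMSE"]).all()
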