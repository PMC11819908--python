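import math
import statistics

import numpy as np
import pytest

from icpredict.models import (
    DOMAIN_NN_WIDTHS,
    InputError,
    ModelSpec,
    SpecError,
    compare_models,
    kfold_cv,
    kfold_folds,
    make_model,
    metrics,
    predict_ic,
    train,
)
from icpredict.nn import DenseRegressor


def brute_force_metrics(y_true, y_pred):
    """Independent oracle: plain-Python recomputation of all four metrics."""
    errs = [p - t for t, p in zip(y_true, y_pred)]
    n = len(errs)
    mse = sum(e * e for e in errs) / n
    mae = sum(abs(e) for e in errs) / n
    medae = statistics.median(abs(e) for e in errs)
    mean_t = sum(y_true) / n
    ss_tot = sum((t - mean_t) ** 2 for t in y_true)
    r2 = float("nan") if ss_tot == 0 else 1 - sum(e * e for e in errs) / ss_tot
    return {"mse": mse, "mae": mae, "r2": r2, "medae": medae}


class TestMetrics:
    def test_perfect_predictor(self):
        out = metrics([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert out == {"mse": 0.0, "mae": 0.0, "r2": 1.0, "medae": 0.0}

    def test_mean_predictor_r2_zero(self):
        y = [0.2, 0.4, 0.9]
        mean = sum(y) / 3
        assert metrics(y, [mean] * 3)["r2"] == pytest.approx(0.0)

    def test_hand_example(self):
        out = metrics([0.0, 1.0], [0.5, 0.5])
        assert out["mse"] == 0.25
        assert out["mae"] == 0.5
        assert out["medae"] == 0.5
        assert out["r2"] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            y_true = rng.random(n)
            y_pred = rng.random(n)
            got = metrics(y_true, y_pred)
            want = brute_force_metrics(list(y_true), list(y_pred))
            for key in ("mse", "mae", "r2", "medae"):
                assert got[key] == pytest.approx(want[key], abs=1e-12)

    def test_constant_target_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            out = metrics([0.5, 0.5], [0.4, 0.6])
        assert math.isnan(out["r2"])

    def test_input_errors(self):
        with pytest.raises(InputError):
            metrics([1.0], [1.0, 2.0])
        with pytest.raises(InputError):
            metrics([], [])


class TestModelSpec:
    def test_unknown_family(self):
        with pytest.raises(SpecError):
            ModelSpec("svm")

    def test_tree_grid_enforced(self):
        with pytest.raises(SpecError):
            ModelSpec("random_forest", tree_count=37)
        assert ModelSpec("random_forest", tree_count=200).tree_count == 200

    def test_nn_requires_widths(self):
        with pytest.raises(SpecError):
            ModelSpec("dense_nn")

    def test_for_domain_widths(self):
        spec = ModelSpec.for_domain("dense_nn", "cognition")
        assert spec.layer_widths == (16, 32, 16)
        assert ModelSpec.for_domain("dense_nn", "locomotion").layer_widths == (32, 32, 32, 32)
        assert ModelSpec.for_domain("dense_nn", "vitality").layer_widths == (8, 16, 16, 8)

    def test_all_domain_widths_declared(self):
        assert set(DOMAIN_NN_WIDTHS) == {
            "locomotion", "sensory", "psychology", "cognition", "vitality"}


class TestMakeModel:
    def test_linear_is_ols(self):
        from sklearn.linear_model import LinearRegression

        assert isinstance(make_model(ModelSpec("linear")), LinearRegression)

    def test_random_forest_tree_count(self):
        model = make_model(ModelSpec("random_forest", tree_count=200))
        assert model.n_estimators == 200

    def test_gradient_boosting_tree_count(self):
        model = make_model(ModelSpec("gradient_boosting", tree_count=10))
        assert model.n_estimators == 10

    def test_dense_nn(self):
        model = make_model(ModelSpec.for_domain("dense_nn", "sensory"))
        assert isinstance(model, DenseRegressor)
        assert model.layer_widths == [16, 16, 16, 16]


class TestTrainPredict:
    def test_noiseless_linear_interpolation(self, rng):
        X = rng.random((50, 3))
        y = 0.2 + X @ np.array([0.1, -0.2, 0.3])
        model = train(make_model(ModelSpec("linear")), X, y)
        assert np.mean((model.predict(X) - y) ** 2) < 1e-20

    def test_predict_clips(self):
        class Raw:
            def predict(self, X):
                return np.array([1.3, -0.1, 0.42])

        out = predict_ic(Raw(), np.zeros((3, 2)))
        assert list(out) == [1.0, 0.0, 0.42]

    def test_unfitted_raises(self):
        model = make_model(ModelSpec("random_forest", tree_count=10))
        with pytest.raises(RuntimeError):
            predict_ic(model, np.zeros((2, 3)))
        with pytest.raises(RuntimeError):
            DenseRegressor([4]).predict(np.zeros((2, 3)))

    def test_train_input_errors(self):
        with pytest.raises(InputError):
            train(make_model(ModelSpec("linear")), np.zeros((3,)), np.zeros(3))
        with pytest.raises(InputError):
            train(make_model(ModelSpec("linear")), np.zeros((0, 2)), np.zeros(0))

    def test_rf_reproducible_with_seed(self, rng):
        X = rng.random((80, 4))
        y = rng.random(80)
        p1 = train(make_model(ModelSpec("random_forest", tree_count=10, seed=7)), X, y).predict(X)
        p2 = train(make_model(ModelSpec("random_forest", tree_count=10, seed=7)), X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_nn_reproducible_with_seed(self, rng):
        X = rng.random((60, 4))
        y = rng.random(60)
        m1 = DenseRegressor([8], max_epochs=5, seed=3).fit(X, y)
        m2 = DenseRegressor([8], max_epochs=5, seed=3).fit(X, y)
        assert np.array_equal(m1.predict(X), m2.predict(X))


class TestKFold:
    @pytest.mark.parametrize("n", [10, 101, 1000])
    def test_partition_properties(self, n):
        folds = kfold_folds(n, 10, seed=42)
        assert len(folds) == 10
        all_test = np.concatenate([t for _, t in folds])
        assert len(all_test) == n
        assert set(all_test) == set(range(n))  # disjoint + exhaustive
        for train_idx, test_idx in folds:
            assert set(train_idx).isdisjoint(test_idx)
            assert len(train_idx) + len(test_idx) == n

    def test_near_equal_sizes(self):
        sizes = [len(t) for _, t in kfold_folds(101, 10, seed=0)]
        assert max(sizes) - min(sizes) <= 1

    def test_seed_reproducible(self):
        a = kfold_folds(50, 10, seed=9)
        b = kfold_folds(50, 10, seed=9)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(sa, sb)
        c = kfold_folds(50, 10, seed=10)
        assert not all(np.array_equal(sa, sc) for (_, sa), (_, sc) in zip(a, c))

    def test_leave_one_out_limit(self):
        folds = kfold_folds(10, 10, seed=1)
        assert all(len(t) == 1 for _, t in folds)

    def test_k_bounds(self):
        with pytest.raises(InputError):
            kfold_folds(5, 10, seed=0)
        with pytest.raises(InputError):
            kfold_folds(5, 1, seed=0)

    def test_cv_average_is_fold_mean(self, rng):
        X = rng.random((40, 3))
        y = 0.3 + X @ np.array([0.2, 0.1, -0.1]) + rng.normal(0, 0.02, 40)
        report = kfold_cv(ModelSpec("linear"), X, y, k=10, seed=0)
        for name in ("mse", "mae", "r2", "medae"):
            assert report.test[name] == pytest.approx(
                np.mean([f[name] for f in report.fold_test]), abs=1e-15)

    def test_cv_perfect_on_noiseless_linear(self, rng):
        X = rng.random((60, 3))
        y = 0.4 + X @ np.array([0.1, 0.05, -0.08])
        report = kfold_cv(ModelSpec("linear"), X, y, k=10, seed=0)
        assert report.test["mae"] < 1e-10
        assert report.test["r2"] == pytest.approx(1.0)


class TestCompare:
    def test_empty_specs(self, rng):
        X = rng.random((20, 2))
        report = compare_models(X, rng.random(20), [], k=5)
        assert report.empty

    def test_layout(self, rng):
        X = rng.random((30, 3))
        y = 0.5 + 0.1 * X[:, 0] + rng.normal(0, 0.02, 30)
        specs = [ModelSpec("linear"), ModelSpec("random_forest", tree_count=10)]
        report = compare_models(X, y, specs, k=5, seed=0)
        assert len(report) == 2
        metric_cols = [c for c in report.columns
                       if c.startswith(("test_", "train_"))]
        assert len(metric_cols) == 8
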