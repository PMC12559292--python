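"""Model fitting, the 7:3 split, metric equations and density mapping."""

import numpy as np
import pytest

from carbonscape.models import (FittedCarbonModel, ModelSpec, evaluate, fit,
                                predict_density_map, split_data, split_indices)

from conftest import make_raster


def brute_force_metrics(y, yhat):
    """Independent re-implementation of the five metrics from their sums."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    n = len(y)
    ybar = sum(y) / n
    sse = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat))
    sst = sum((yi - ybar) ** 2 for yi in y)
    rmse = (sse / n) ** 0.5
    return {
        "r2": 1 - sse / sst,
        "rmse": rmse,
        "rrmse": rmse / ybar,
        "mae": sum(abs(yi - yh) for yi, yh in zip(y, yhat)) / n,
        "mbe": sum(yi - yh for yi, yh in zip(y, yhat)) / n,
    }


class TestSplit:
    def test_seven_three_sizes(self):
        tr, te = split_indices(10, 0.7, seed=0)
        assert len(tr) == 7 and len(te) == 3

    def test_partition_and_determinism(self):
        tr1, te1 = split_indices(23, 0.7, seed=5)
        tr2, te2 = split_indices(23, 0.7, seed=5)
        np.testing.assert_array_equal(tr1, tr2)
        assert sorted(np.concatenate([tr1, te1])) == list(range(23))
        assert set(tr1).isdisjoint(te1)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_indices(10, 1.2, seed=0)

    def test_split_data_consistent_with_indices(self):
        X = np.arange(20.0).reshape(10, 2)
        y = np.arange(10.0)
        (Xtr, ytr), (Xte, yte) = split_data(X, y, seed=3)
        assert len(ytr) == 7 and len(yte) == 3
        np.testing.assert_array_equal(Xtr[:, 0] / 2.0, ytr)


class TestFit:
    def test_mlr_exact_recovery_on_noiseless_line(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(40, 1))
        y = 2.0 + 3.0 * X[:, 0]
        m = fit(ModelSpec(kind="mlr"), X, y)
        np.testing.assert_allclose(m.coefficients, [2.0, 3.0], atol=1e-9)
        assert m.test_metrics.rmse == pytest.approx(0.0, abs=1e-9)

    def test_mlr_recovery_within_three_se_with_noise(self):
        rng = np.random.default_rng(42)
        n, sigma = 200, 0.5
        X = rng.uniform(0, 2, size=(n, 2))
        beta = np.array([1.0, 2.5, -1.5])
        y = beta[0] + X @ beta[1:] + rng.normal(0, sigma, n)
        m = fit(ModelSpec(kind="mlr"), X, y, evaluate_split=False)
        A = np.column_stack([np.ones(n), X])
        cov = sigma ** 2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(m.coefficients - beta) < 3 * se)

    def test_mlr_rank_deficiency_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit(ModelSpec(kind="mlr"), X, np.arange(10.0))

    def test_dt_respects_max_depth(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(200, 3))
        y = rng.uniform(size=200)
        m = fit(ModelSpec(kind="dt"), X, y)
        assert m.estimator.get_depth() <= 4

    def test_rf_deterministic_given_seeds(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(60, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        m1 = fit(ModelSpec(kind="rf"), X, y)
        m2 = fit(ModelSpec(kind="rf"), X, y)
        grid = rng.uniform(size=(30, 2))
        np.testing.assert_array_equal(m1.predict(grid), m2.predict(grid))

    def test_rf_hyperparameter_defaults(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(30, 2))
        m = fit(ModelSpec(kind="rf"), X, X[:, 0])
        est = m.estimator
        assert (est.n_estimators, est.max_depth, est.min_samples_split,
                est.random_state) == (100, 5, 3, 42)

    def test_mlr_scale_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(50, 2))
        y = 1.0 + X @ np.array([2.0, -1.0]) + rng.normal(0, 0.1, 50)
        m = fit(ModelSpec(kind="mlr"), X, y, evaluate_split=False)
        m_scaled = fit(ModelSpec(kind="mlr"), X * 10.0, y, evaluate_split=False)
        np.testing.assert_allclose(m_scaled.coefficients[1:],
                                   m.coefficients[1:] / 10.0, atol=1e-9)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = evaluate(y, y)
        assert (m.r2, m.rmse, m.rrmse, m.mae, m.mbe) == (1.0, 0.0, 0.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = evaluate(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_values(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert m.rmse == pytest.approx(0.57735, abs=1e-5)
        assert m.mae == pytest.approx(1 / 3)
        assert m.mbe == pytest.approx(-1 / 3)  # observed - predicted
        assert m.r2 == pytest.approx(0.5)
        assert m.rrmse == pytest.approx(0.28868, abs=1e-5)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            y = rng.uniform(1, 50, size=rng.integers(5, 60))
            yhat = y + rng.normal(0, 5, size=y.size)
            m = evaluate(y, yhat)
            ref = brute_force_metrics(y, yhat)
            for k, v in ref.items():
                assert getattr(m, k) == pytest.approx(v, abs=1e-12)

    def test_printed_rrmse_variant(self):
        y = np.array([1.0, 2.0, 3.0])
        m = evaluate(y, [1.0, 2.0, 4.0], as_printed=True)
        assert m.rrmse == pytest.approx(np.sqrt((1 / 3) / 2.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPredictDensityMap:
    def _intercept_model(self, value):
        return FittedCarbonModel(
            spec=ModelSpec(kind="mlr", predictor_names=("NDVI",)),
            predictor_names=("NDVI",),
            coefficients=np.array([value, 0.0]))

    def test_intercept_only_gives_uniform_map(self):
        ndvi = make_raster(np.random.default_rng(0).uniform(0, 1, (5, 5)))
        mask = np.ones((5, 5), bool)
        mask[0, 0] = False
        out, n_floored = predict_density_map(
            self._intercept_model(5.0), {"NDVI": ndvi}, mask)
        assert np.all(out.data[mask] == 5.0)
        assert out.mask[0, 0] and n_floored == 0

    def test_empty_mask_all_nodata(self):
        ndvi = make_raster(np.ones((4, 4)))
        out, _ = predict_density_map(
            self._intercept_model(5.0), {"NDVI": ndvi}, np.zeros((4, 4), bool))
        assert out.mask.all()

    def test_negative_predictions_floored_and_counted(self):
        ndvi = make_raster(np.ones((3, 3)))
        out, n_floored = predict_density_map(
            self._intercept_model(-2.0), {"NDVI": ndvi}, np.ones((3, 3), bool))
        assert np.all(out.data[~out.mask] == 0.0)
        assert n_floored == 9

    def test_missing_predictor_named(self):
        ndvi = make_raster(np.ones((3, 3)))
        model = FittedCarbonModel(
            spec=ModelSpec(kind="mlr"), predictor_names=("NDVI", "SAVI"),
            coefficients=np.array([0.0, 1.0, 1.0]))
        with pytest.raises(KeyError, match="SAVI"):
            predict_density_map(model, {"NDVI": ndvi}, np.ones((3, 3), bool))

    def test_rf_recovers_noiseless_scene_pattern(self):
        rng = np.random.default_rng(5)
        ndvi = rng.uniform(0, 1, (40, 40))
        density = 5.0 + 40.0 * ndvi
        X = ndvi.ravel().reshape(-1, 1)
        m = fit(ModelSpec(kind="rf", predictor_names=("NDVI",)), X,
                density.ravel(), evaluate_split=False)
        out, _ = predict_density_map(
            m, {"NDVI": make_raster(ndvi)}, np.ones((40, 40), bool))
        ss_res = np.sum((out.data - density) ** 2)
        ss_tot = np.sum((density - density.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.8
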