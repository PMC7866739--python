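"""Tests for fit metrics, σ tuning and the evaluation pipeline."""

import numpy as np
import pandas as pd
import pytest

import grnnfoa as g
from grnnfoa.evaluate import _CVObjective
from grnnfoa.preprocess import make_cv_plan, ScalingState


class TestMetrics:
    def test_perfect_fit(self, rng):
        y = rng.normal(size=20)
        m = g.compute_metrics(y, y)
        assert m == {"rmse": 0.0, "mbe": 0.0, "r2": 1.0}

    def test_worked_two_point_example(self):
        m = g.compute_metrics([1.0, 3.0], [2.0, 4.0])
        assert m["mbe"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(1.0)
        assert m["r2"] == pytest.approx(0.0)

    def test_constant_shift_moves_mbe_exactly(self, rng):
        y = rng.normal(size=30)
        est = y + rng.normal(scale=0.3, size=30)
        base = g.compute_metrics(y, est)["mbe"]
        shifted = g.compute_metrics(y, est + 1.7)["mbe"]
        assert shifted - base == pytest.approx(1.7, abs=1e-12)

    def test_error_decomposition_identity(self, rng):
        # RMSE^2 = MBE^2 + var(residuals)
        for _ in range(20):
            y = rng.normal(size=25)
            est = y + rng.normal(size=25)
            m = g.compute_metrics(y, est)
            resid_var = np.var(est - y)
            assert m["rmse"] ** 2 == pytest.approx(m["mbe"] ** 2 + resid_var, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            g.compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            g.compute_metrics([1.0, 2.0], [1.0])


def _toy_regression(n=80, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-2, 2, size=(n, 2))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + noise * rng.standard_normal(n)
    return X, y


class TestSigmaTuning:
    def test_matches_exhaustive_grid_on_smooth_targets(self):
        X, y = _toy_regression()
        Xs = ScalingState.fit(X).apply(X)
        plan = make_cv_plan(len(y), k=5, repeats=2, seed=0)
        obj = _CVObjective(Xs, y, plan, None)
        sigma = g.tune_sigma_foa(Xs, y, plan, g.FOAConfig(seed=0))
        grid = np.logspace(-3, 1, 200)
        best_grid = min(obj.mean_rmse(s) for s in grid)
        assert obj.mean_rmse(sigma) <= 1.05 * best_grid

    def test_pure_noise_targets_drift_to_flat_kernel(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(100, 2))
        y = rng.standard_normal(100)
        Xs = ScalingState.fit(X).apply(X)
        plan = make_cv_plan(100, k=5, repeats=2, seed=0)
        sigma = g.tune_sigma_foa(Xs, y, plan, g.FOAConfig(seed=0))
        obj = _CVObjective(Xs, y, plan, None)
        # flat-kernel limit: the model degenerates to the training mean,
        # whose CV RMSE approaches the target standard deviation
        assert sigma > 1.0
        assert obj.mean_rmse(sigma) == pytest.approx(y.std(), rel=0.15)

    def test_deterministic_under_seed(self):
        X, y = _toy_regression(noise=0.2)
        Xs = ScalingState.fit(X).apply(X)
        plan = make_cv_plan(len(y), k=5, repeats=2, seed=0)
        s1 = g.tune_sigma_foa(Xs, y, plan, g.FOAConfig(seed=9))
        s2 = g.tune_sigma_foa(Xs, y, plan, g.FOAConfig(seed=9))
        assert s1 == s2

    def test_too_few_rows_rejected(self):
        X, y = _toy_regression(n=8)
        plan = make_cv_plan(8, k=5, repeats=1, seed=0)
        with pytest.raises(ValueError, match="2k"):
            g.tune_sigma_foa(X, y, plan)


class TestPipeline:
    def test_interpolation_limit_on_noiseless_replicates(self, small_dataset):
        # in-fold predictions at a tiny bandwidth reproduce the fold's
        # own targets, so the training R^2 approaches 1
        df = small_dataset
        X = df[g.INPUT_COLUMNS].to_numpy()
        Xs = ScalingState.fit(X).apply(X)
        y = df["total_ug_l"].to_numpy()
        plan = make_cv_plan(len(df), k=5, repeats=1, seed=0)
        obj = _CVObjective(Xs, y, plan, None)
        for tr, _te, pred_tr, _pred_te in obj.fold_predictions(1e-4):
            assert g.compute_metrics(y[tr], pred_tr)["r2"] > 0.999

    def test_metrics_table_shape_and_aggregation(self, small_dataset):
        cfg = g.PipelineConfig(seed=1, cv_repeats=2, foa_maxgen=15)
        pipe = g.evaluate_pipeline(small_dataset, cfg, responses=["dw_g_l"])
        met = pipe.metrics
        assert set(met.subset) == {"training", "testing"}
        assert {"r2", "rmse", "mbe", "r2_sd", "rmse_sd", "mbe_sd"} <= set(met.columns)
        assert (met.rmse >= 0).all()
        test_row = met[met.subset == "testing"].iloc[0]
        assert test_row.r2 > 0.5  # held-out skill on a strong signal

    def test_pipeline_round_trip_replays_predictions(self, small_pipeline, small_dataset, tmp_path):
        path = tmp_path / "pipe.json"
        small_pipeline.save(path)
        clone = g.FittedPipeline.load(path)
        X = small_dataset[g.INPUT_COLUMNS].to_numpy()[:13]
        for resp in small_pipeline.responses:
            np.testing.assert_array_equal(
                small_pipeline.predict(resp, X), clone.predict(resp, X)
            )

    def test_sigma_shared_across_folds_and_recorded(self, small_pipeline):
        for resp, model in small_pipeline.models.items():
            assert model.sigma == small_pipeline.sigmas[resp] > 0

    def test_missing_response_column_rejected(self, small_dataset):
        with pytest.raises(Exception, match="cf_pct"):
            g.evaluate_pipeline(small_dataset.drop(columns=["cf_pct"]))
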