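"""Lagged design, CV-ridge TRF estimation, prediction."""

import numpy as np
import pytest

from spikereadout import (
    FeatureMatrix,
    LagSpec,
    TemporalReceptiveField,
    build_lagged_design,
)


def test_lagged_design_definition():
    fm = FeatureMatrix(np.array([[1.0], [2.0], [3.0]]), 20.0)
    design = build_lagged_design(fm, LagSpec(window=0.1, rate=20.0))
    np.testing.assert_array_equal(design, [[0, 1], [1, 2], [2, 3]])


def test_lagged_design_single_lag_identity():
    fm = FeatureMatrix(np.random.default_rng(0).standard_normal((7, 3)), 20.0)
    design = build_lagged_design(fm, LagSpec(window=0.05, rate=20.0))
    np.testing.assert_array_equal(design, fm.values)


def test_lagged_design_rate_mismatch_rejected():
    fm = FeatureMatrix(np.zeros((5, 1)), 50.0)
    with pytest.raises(ValueError):
        build_lagged_design(fm, LagSpec(rate=20.0))


@pytest.mark.parametrize("rate,n_lags", [(20.0, 5), (50.0, 13)])
def test_250ms_window_lag_counts(rate, n_lags):
    # round-half-up: 0.25 * 50 = 12.5 -> 13
    assert LagSpec(window=0.25, rate=rate).n_lags == n_lags


def _closed_form_ridge(X, y, lam):
    ym = y.mean()
    w = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ (y - ym))
    return w, ym


def test_ridge_matches_closed_form_on_random_instances():
    """CV-ridge at a single penalty equals (X'X + lam I)^-1 X'(y - ybar)."""
    rng = np.random.default_rng(0)
    worst = 0.0
    for trial in range(100):
        n = int(rng.integers(8, 21))
        d = int(rng.integers(1, 6))
        X = rng.standard_normal((n, d))
        y = rng.standard_normal(n)
        lam = 10.0 ** rng.uniform(-3, 3)
        fm = FeatureMatrix(X, 20.0)
        res = TemporalReceptiveField(
            y, fm, window=0.05, lambda_grid=np.array([lam]), standardize=False
        ).fit(k_folds=3, seed=0)
        w_ref, ym = _closed_form_ridge(X, y, lam)
        rel = np.linalg.norm(res.coef_ - w_ref) / (np.linalg.norm(w_ref) + 1e-30)
        worst = max(worst, rel)
        assert res.intercept == pytest.approx(ym, abs=1e-8)
    assert worst < 1e-6


def test_heavy_penalty_shrinks_weights():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((60, 4))
    y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.1 * rng.standard_normal(60)
    fm = FeatureMatrix(X, 20.0)
    ols = TemporalReceptiveField(
        y, fm, window=0.05, lambda_grid=np.array([1e-10]), standardize=False
    ).fit(seed=0)
    heavy = TemporalReceptiveField(
        y, fm, window=0.05, lambda_grid=np.array([1e15]), standardize=False
    ).fit(seed=0)
    assert np.linalg.norm(heavy.coef_) < 1e-6 * np.linalg.norm(ols.coef_)


def test_noiseless_linear_map_recovered():
    rng = np.random.default_rng(2)
    fm = FeatureMatrix(rng.standard_normal((300, 3)), 20.0)
    w_true = rng.standard_normal(3 * 5)
    design = build_lagged_design(fm, LagSpec(0.25, 20.0))
    y = design @ w_true + 1.5
    res = TemporalReceptiveField(y, fm, window=0.25).fit(seed=0)
    assert res.lambda_ <= 1e-3  # CV picks (near) the smallest penalty
    assert res.training_correlation() > 0.9999
    np.testing.assert_allclose(res.coef_, w_true, atol=1e-3)


def test_cv_curve_recorded_and_reproducible():
    rng = np.random.default_rng(3)
    fm = FeatureMatrix(rng.standard_normal((120, 2)), 20.0)
    y = fm.values[:, 0] + 0.5 * rng.standard_normal(120)
    model = TemporalReceptiveField(y, fm)
    a, b = model.fit(seed=1), model.fit(seed=1)
    assert a.cv_curve.shape == model.lambda_grid.shape
    np.testing.assert_array_equal(a.cv_curve, b.cv_curve)
    assert a.lambda_ == b.lambda_
    assert a.lambda_ in model.lambda_grid


def test_degenerate_design_flagged():
    fm = FeatureMatrix(np.zeros((30, 2)), 20.0)
    y = np.random.default_rng(0).poisson(1.0, 30).astype(float)
    res = TemporalReceptiveField(y, fm).fit(seed=0)
    assert res.flagged
    np.testing.assert_array_equal(res.coef_, 0.0)
    pred = res.predict(fm)
    np.testing.assert_allclose(pred, y.mean())


def test_predict_dimension_mismatch_rejected():
    fm = FeatureMatrix(np.random.default_rng(0).standard_normal((40, 2)), 20.0)
    res = TemporalReceptiveField(fm.values[:, 0], fm).fit(seed=0)
    with pytest.raises(ValueError):
        res.predict(FeatureMatrix(np.zeros((10, 3)), 20.0))


def test_lags_do_not_cross_stimulus_boundaries():
    rng = np.random.default_rng(4)
    f1 = FeatureMatrix(rng.standard_normal((50, 1)), 20.0)
    f2 = FeatureMatrix(rng.standard_normal((50, 1)), 20.0)
    model = TemporalReceptiveField(
        [f1.values[:, 0], f2.values[:, 0]], [f1, f2], window=0.25
    )
    design = model.exog
    # first rows of the second stimulus are zero-padded, not fed from f1
    np.testing.assert_array_equal(design[50, :4], 0.0)


def test_summary_mentions_key_quantities():
    fm = FeatureMatrix(np.random.default_rng(0).standard_normal((60, 2)), 20.0)
    res = TemporalReceptiveField(fm.values[:, 0], fm).fit(seed=0)
    text = res.summary()
    assert "lambda" in text and "lags" in text
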