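"""Clock fitting: penalised-regression oracles, CV contracts, predictions."""

import json

import numpy as np
import pandas as pd
import pytest

from protclock.clock import (
    FeatureMismatchError,
    clock_metrics,
    default_lambda_grid,
    fit_clock,
    fit_clock_sex_stratified,
    predict_and_accelerate,
    _fit_at_lambda,
    _standardise,
)
from protclock.synthgen import SimConfig, simulate_cohort

from conftest import make_cohort


def _complete_cohort(n=50, p=3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    age = 55 + x @ rng.normal(size=p) + rng.normal(scale=0.5, size=n)
    c = make_cohort(x, age=age)
    return c


def test_lambda_zero_fit_equals_ols():
    cohort = _complete_cohort()
    model = fit_clock(cohort, lambda_grid=np.array([0.0]), n_folds=5, seed=1)
    X = np.column_stack([np.ones(cohort.n_samples), cohort.proteins.to_numpy()])
    y = cohort.phenotypes["age"].to_numpy()
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(model.intercept, ols[0], atol=1e-6)
    np.testing.assert_allclose(model.coefficients.to_numpy(), ols[1:], atol=1e-6)


def test_lasso_single_feature_matches_soft_threshold():
    """alpha=1, one standardised feature: beta = S(<x,y>/n, lambda)."""
    rng = np.random.default_rng(4)
    n = 200
    x = rng.normal(size=(n, 1))
    y = 50 + 0.8 * x[:, 0] + rng.normal(scale=0.3, size=n)
    cohort = make_cohort(x, age=y)
    for lam in (0.05, 0.3, 2.0):
        model = fit_clock(cohort, alpha=1.0, lambda_grid=np.array([lam]),
                          n_folds=5, seed=0)
        xs, _, sd = _standardise(x)
        rho = float(xs[:, 0] @ (y - y.mean())) / n
        expected_std = np.sign(rho) * max(abs(rho) - lam, 0.0)
        got_std = model.coefficients.iloc[0] * sd[0]
        assert got_std == pytest.approx(expected_std, abs=1e-8)


def test_chosen_lambda_minimises_cv_rmse(small_cohort):
    cohort, _, _ = small_cohort
    model = fit_clock(cohort, seed=3)
    i = int(np.flatnonzero(model.lambda_grid == model.lam)[0])
    assert model.cv_rmse[i] <= model.cv_rmse.min() + 1e-12
    assert len(model.cv_rmse) == len(model.lambda_grid)


def test_l1_norm_shrinks_monotonically_with_lambda(small_cohort):
    cohort, _, _ = small_cohort
    x = cohort.proteins.to_numpy()
    y = cohort.phenotypes["age"].to_numpy()
    xs, _, _ = _standardise(x)
    yc = y - y.mean()
    norms = [
        np.abs(_fit_at_lambda(xs, yc, lam, 0.5)).sum()
        for lam in (0.01, 0.05, 0.2, 0.8)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


def test_default_grid_contains_the_canonical_small_penalty():
    grid = default_lambda_grid()
    assert 1e-3 in grid
    assert grid.min() == pytest.approx(1e-4) and grid.max() == pytest.approx(1.0)


def test_zero_coefficient_model_predicts_intercept(small_cohort):
    cohort, _, _ = small_cohort
    # huge penalty drives every coefficient to zero
    model = fit_clock(cohort, lambda_grid=np.array([1e6]), seed=0)
    assert (model.coefficients == 0).all()
    pred = predict_and_accelerate(model, cohort)
    np.testing.assert_allclose(pred.predicted_age, model.intercept)


def test_training_predictions_have_zero_mean_residual(small_cohort):
    cohort, _, _ = small_cohort
    model = fit_clock(cohort, seed=3)
    pred = predict_and_accelerate(model, cohort)
    assert pred.predicted_age.mean() == pytest.approx(
        pred.chronological_age.mean(), abs=1e-8
    )


def test_acceleration_identity_and_permutation_equivariance(small_cohort):
    cohort, _, _ = small_cohort
    model = fit_clock(cohort, seed=3)
    pred = predict_and_accelerate(model, cohort)
    np.testing.assert_array_equal(
        pred.acceleration, pred.predicted_age - pred.chronological_age
    )
    rng = np.random.default_rng(0)
    perm = rng.permutation(cohort.n_samples)
    from protclock.synthgen import Cohort

    shuffled = Cohort(cohort.phenotypes.iloc[perm], cohort.proteins.iloc[perm])
    pred2 = predict_and_accelerate(model, shuffled)
    np.testing.assert_allclose(pred2.predicted_age, pred.predicted_age[perm])


def test_missing_model_feature_raises(small_cohort):
    cohort, _, _ = small_cohort
    model = fit_clock(cohort, seed=3)
    from protclock.synthgen import Cohort

    crippled = Cohort(cohort.phenotypes, cohort.proteins.iloc[:, 5:].copy())
    with pytest.raises(FeatureMismatchError):
        predict_and_accelerate(model, crippled)


def test_nonfinite_matrix_rejected():
    x = np.ones((20, 2))
    x[3, 1] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_clock(make_cohort(x), n_folds=2)


def test_empty_lambda_grid_rejected(small_cohort):
    cohort, _, _ = small_cohort
    with pytest.raises(ValueError, match="lambda_grid"):
        fit_clock(cohort, lambda_grid=np.array([]))


@pytest.mark.parametrize(
    "shift,expected_r,expected_mae",
    [(0.0, 1.0, 0.0), (2.0, 1.0, 2.0)],
)
def test_metrics_on_exact_predictions(shift, expected_r, expected_mae):
    from protclock.clock import AgePrediction

    age = np.array([40.0, 50.0, 60.0, 70.0])
    pred = AgePrediction(pd.RangeIndex(4), age + shift, age, np.full(4, shift))
    m = clock_metrics(pred)
    assert m["pearson_r"] == pytest.approx(expected_r)
    assert m["mae_years"] == pytest.approx(expected_mae)


def test_metrics_degenerate_inputs_raise():
    from protclock.clock import AgePrediction

    with pytest.raises(ValueError):
        clock_metrics(AgePrediction(pd.RangeIndex(2), np.ones(2), np.ones(2), np.zeros(2)))
    flat = AgePrediction(pd.RangeIndex(4), np.ones(4), np.arange(4.0), None)
    with pytest.raises(ValueError, match="zero variance"):
        clock_metrics(flat)


def test_excluded_proteins_absent_from_model(small_cohort):
    cohort, _, _ = small_cohort
    drop = set(cohort.protein_ids[:3])
    model = fit_clock(cohort, seed=3, excluded_proteins=drop)
    assert model.excluded_proteins == frozenset(drop)
    assert not set(model.features) & drop
    pred = predict_and_accelerate(model, cohort)  # superset cohort is fine
    assert np.isfinite(pred.predicted_age).all()


def test_sex_stratified_models_cover_all_samples_once(small_cohort):
    cohort, _, _ = small_cohort
    models = fit_clock_sex_stratified(cohort, seed=3)
    covered = []
    for stratum, model in models.items():
        rows = cohort.phenotypes["sex"] == stratum
        covered += list(cohort.sample_ids[rows])
        assert set(model.fold_assignment.index) == set(cohort.sample_ids[rows])
    assert sorted(covered) == sorted(cohort.sample_ids)


def test_model_json_roundtrip(tmp_path, small_cohort):
    cohort, _, _ = small_cohort
    model = fit_clock(cohort, seed=3)
    path = tmp_path / "model.json"
    model.to_json(path)
    payload = json.loads(path.read_text())
    assert payload["alpha"] == 0.5
    assert payload["lambda"] == model.lam
    np.testing.assert_allclose(
        [payload["coefficients"][p] for p in model.features],
        model.coefficients.to_numpy(),
    )


def test_clock_learns_age_on_synthetic_cohort(small_cohort):
    """End-to-end sanity: R and MAE in the regime the generator targets."""
    cohort, _, _ = small_cohort
    model = fit_clock(cohort, seed=3)
    pred = predict_and_accelerate(model, cohort)
    m = clock_metrics(pred)
    assert m["pearson_r"] > 0.8
    assert m["mae_years"] < 4.5


def test_out_of_fold_metrics_match_independent_refit(small_cohort):
    """Cross-validated R agrees with an independent sklearn re-implementation."""
    from sklearn.linear_model import ElasticNet
    from sklearn.preprocessing import StandardScaler

    from protclock.clock import cross_validated_predictions

    cohort, _, _ = small_cohort
    model = fit_clock(cohort, seed=3)
    cv_pred = cross_validated_predictions(cohort, model)
    # independent oracle: same folds/lambda, sklearn pipeline with its own
    # standardisation and intercept handling
    x = cohort.proteins[model.features].to_numpy()
    y = cohort.phenotypes["age"].to_numpy()
    folds = model.fold_assignment.to_numpy()
    oracle = np.empty_like(y)
    for k in np.unique(folds):
        tr, va = folds != k, folds == k
        scaler = StandardScaler().fit(x[tr])
        en = ElasticNet(alpha=model.lam, l1_ratio=model.alpha, max_iter=50_000)
        en.fit(scaler.transform(x[tr]), y[tr])
        oracle[va] = en.predict(scaler.transform(x[va]))
    r_ours = clock_metrics(cv_pred)["pearson_r"]
    r_oracle = np.corrcoef(oracle, y)[0, 1]
    assert r_ours == pytest.approx(r_oracle, abs=0.03)
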