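"""Outcome regressions, Cox survival, Schoenfeld diagnostics, Kaplan-Meier."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from protclock.outcomes import (
    cox_score_test_at_zero,
    fit_cox,
    km_estimate,
    outcome_regression,
    schoenfeld_ph_test,
    top_decile_groups,
)


def test_logistic_recovery_of_latent_risk_effect():
    """logit(p) = -3 + 0.08*x gives OR ~ exp(0.08) on the exposure."""
    rng = np.random.default_rng(0)
    n = 8000
    x = rng.normal(55, 8, size=n)  # proteomic age
    chron = rng.normal(55, 8, size=n)  # independent chronological age
    logit = -3 + 0.08 * (x - 55)
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float))
    tab = outcome_regression(y, x, chron, family="binary")
    row = tab.loc["proteomic_age"]
    assert row["estimable"]
    se = (np.log(row["hi"]) - np.log(row["lo"])) / (2 * 1.96)
    assert abs(np.log(row["effect"]) - 0.08) <= 2 * se


def test_continuous_exact_linear_outcome():
    rng = np.random.default_rng(1)
    n = 200
    prot = rng.normal(size=n)
    chron = rng.normal(size=n)
    y = pd.Series(1.0 + 2.0 * prot - 0.5 * chron + 0.1 * chron**2)
    tab = outcome_regression(y, prot, chron, family="continuous")
    assert tab.loc["proteomic_age", "effect"] == pytest.approx(2.0, abs=1e-8)
    assert tab.loc["chronological_age", "effect"] == pytest.approx(-0.5, abs=1e-8)


def test_degenerate_binary_outcome_raises():
    y = pd.Series(np.zeros(50))
    with pytest.raises(ValueError, match="degenerate"):
        outcome_regression(y, np.arange(50.0), np.arange(50.0), family="binary")


def test_perfect_separation_flagged_not_estimated():
    x = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)])
    y = pd.Series((x > 0).astype(float))
    chron = np.random.default_rng(2).normal(size=40)
    tab = outcome_regression(y, x, chron, family="binary")
    assert not tab["estimable"].any()
    assert tab["effect"].isna().all()


def test_cox_recovers_hazard_ratio_two():
    rng = np.random.default_rng(3)
    n = 2000
    g = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2) * g)))
    fit = fit_cox(t, np.ones(n), pd.DataFrame({"g": g}))
    row = fit.table.loc["g"]
    assert abs(row["beta"] - np.log(2)) <= 2 * row["se"]
    assert row["hr"] == pytest.approx(np.exp(row["beta"]))
    assert row["hr_lo"] == pytest.approx(np.exp(row["beta"] - 1.96 * row["se"]))


def test_cox_constant_covariate_rejected():
    with pytest.raises(ValueError, match="constant covariate"):
        fit_cox(np.arange(1.0, 11.0), np.ones(10), pd.DataFrame({"c": np.ones(10)}))


def test_cox_requires_events_and_positive_times():
    cov = pd.DataFrame({"x": np.random.default_rng(0).normal(size=10)})
    with pytest.raises(ValueError, match="event"):
        fit_cox(np.arange(1.0, 11.0), np.zeros(10), cov)
    with pytest.raises(ValueError, match="positive"):
        fit_cox(np.arange(0.0, 10.0), np.ones(10), cov)


def test_cox_invariant_to_centring_and_time_units():
    rng = np.random.default_rng(4)
    n = 500
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
    e = (t < 20).astype(float)
    t = np.minimum(t, 20)
    base = fit_cox(t, e, pd.DataFrame({"x": x}))
    centred = fit_cox(t, e, pd.DataFrame({"x": x + 100}))
    rescaled = fit_cox(t * 365.25, e, pd.DataFrame({"x": x}))
    assert centred.table.loc["x", "beta"] == pytest.approx(
        base.table.loc["x", "beta"], rel=1e-6)
    assert rescaled.table.loc["x", "hr"] == pytest.approx(
        base.table.loc["x", "hr"], rel=1e-6)


def test_score_test_matches_logrank_statistic():
    """Cox score test at beta=0 equals the log-rank chi-square (distinct times)."""
    rng = np.random.default_rng(5)
    n = 300
    g = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(0.7 * g)))
    assert len(np.unique(t)) == n  # continuous draws: no ties
    ours = cox_score_test_at_zero(t, np.ones(n), g)
    lr = logrank_test(t[g == 0], t[g == 1])
    assert ours == pytest.approx(lr.test_statistic, abs=1e-6)


def test_schoenfeld_outputs_per_covariate_and_global():
    rng = np.random.default_rng(6)
    n = 800
    x = rng.normal(size=n)
    z = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(0.3 * x)))
    e = (t < 15).astype(float)
    fit = fit_cox(np.minimum(t, 15), e, pd.DataFrame({"x": x, "z": z}))
    out = schoenfeld_ph_test(fit)
    assert set(out.index) == {"x", "z", "GLOBAL"}
    assert ((out["p"] > 0) & (out["p"] <= 1)).all()


def test_schoenfeld_detects_time_varying_effect():
    """A strongly time-increasing effect should be flagged at n=2000."""
    rng = np.random.default_rng(7)
    n = 2000
    x = rng.normal(size=n)
    # piecewise: x is protective early, harmful late -> non-proportional
    u = rng.random(n)
    t_early = rng.exponential(1.0 / (0.25 * np.exp(-0.8 * x)))
    t_late = 2.0 + rng.exponential(1.0 / (0.25 * np.exp(0.8 * x)))
    t = np.where(u < 0.5, np.minimum(t_early, 2.0 - 1e-9), t_late)
    fit = fit_cox(t, np.ones(n), pd.DataFrame({"x": x}))
    out = schoenfeld_ph_test(fit)
    assert out.loc["x", "p"] < 0.05


def test_schoenfeld_single_event_raises():
    t = np.array([1.0, 2.0, 3.0])
    e = np.array([1.0, 0.0, 0.0])
    x = np.array([0.0, 1.0, 2.0])
    fit = fit_cox(t, e, pd.DataFrame({"x": x}))
    with pytest.raises(ValueError, match="2 events"):
        schoenfeld_ph_test(fit)


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(8)
    t = rng.exponential(5.0, size=200)
    groups = np.array(["a", "b"] * 100)
    km, _ = km_estimate(t, np.ones(200), groups)
    for label in ("a", "b"):
        sel = groups == label
        curve = km[km["group"] == label]
        for _, row in curve.iloc[1:].iterrows():
            emp = (t[sel] > row["time"]).mean()
            assert row["survival"] == pytest.approx(emp, abs=1e-12)


def test_km_hand_computed_five_subjects():
    """5 subjects, all events at distinct times: S = prod(1 - 1/n_i)."""
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 1.5, 2.5, 3.5, 4.5, 5.5])
    g = np.array(["x"] * 5 + ["y"] * 5)
    km, _ = km_estimate(t, np.ones(10), g)
    x_curve = km[km["group"] == "x"]["survival"].to_numpy()
    np.testing.assert_allclose(x_curve, [1.0, 0.8, 0.6, 0.4, 0.2, 0.0], atol=1e-12)


def test_km_survival_starts_at_one_and_never_increases():
    rng = np.random.default_rng(9)
    t = rng.exponential(5.0, size=100)
    e = rng.integers(0, 2, 100).astype(float)
    e[0] = 1  # ensure at least one event per group
    e[1] = 1
    km, p = km_estimate(t, e, np.array(["a", "b"] * 50))
    for label in ("a", "b"):
        s = km[km["group"] == label]["survival"].to_numpy()
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()
    assert 0 <= p <= 1


def test_km_empty_group_rejected():
    with pytest.raises(ValueError):
        km_estimate(np.array([1.0]), np.array([1.0]), np.array(["only"]))


def test_top_decile_grouping_is_age_adjusted():
    rng = np.random.default_rng(10)
    n = 1000
    age = rng.uniform(40, 70, n)
    offset = rng.normal(0, 3, n)
    predicted = age + offset
    labels = top_decile_groups(predicted, age)
    assert (labels == "oldest10").mean() == pytest.approx(0.10, abs=0.01)
    # the adjustment means the oldest decile is driven by the offset, not age
    assert offset[labels == "oldest10"].mean() > offset.mean() + 2 * offset.std() / 3
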