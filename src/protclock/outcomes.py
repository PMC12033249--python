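"""Phenotypic associations of proteomic age: disease, traits, and mortality.

Three designs:

* **Outcome regressions** — logistic (binary outcomes) or OLS (continuous),
  with design matrix [1, proteomic_age, chronological_age,
  chronological_age^2, (sex)], reporting effect, 95% CI and p for both the
  proteomic- and chronological-age terms. The squared age term absorbs
  curvature so the proteomic term is not credited with simple nonlinearity
  in age.
* **Cox proportional hazards** of all-cause mortality on proteomic age (or
  acceleration), adjusted for age at recruitment and sex, with a Schoenfeld
  residual check of the proportional-hazards assumption.
* **Kaplan-Meier curves** comparing the decile with the oldest proteomic
  age (after residualising predicted age on chronological age) against the
  rest, with Greenwood confidence bands and a log-rank test.

Model fitting is delegated to statsmodels (GLM/OLS) and lifelines
(CoxPHFitter, Kaplan-Meier, PH test); this module owns the designs,
wrappers and the small score test used for cross-checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

__all__ = [
    "SurvivalFit",
    "outcome_regression",
    "fit_cox",
    "schoenfeld_ph_test",
    "km_estimate",
    "top_decile_groups",
    "cox_score_test_at_zero",
]

logger = logging.getLogger(__name__)


@dataclass
class SurvivalFit:
    """Cox model results: log-hazards, HRs with 95% CIs, diagnostics."""

    table: pd.DataFrame  # index covariate; columns beta, se, hr, hr_lo, hr_hi, p
    baseline_cumhaz: pd.DataFrame
    n: int
    n_events: int
    log_likelihood: float
    fitter: CoxPHFitter
    data: pd.DataFrame
    duration_col: str
    event_col: str


def outcome_regression(
    outcome: pd.Series,
    predicted_age: np.ndarray | pd.Series,
    chronological_age: np.ndarray | pd.Series,
    sex: pd.Series | None = None,
    family: str = "binary",
) -> pd.DataFrame:
    """Association of an outcome with proteomic age, adjusted for age and age^2.

    Binary outcomes use logistic regression (IRLS) and report odds ratios;
    continuous outcomes use OLS and report betas. Columns: effect, lo, hi, p
    (CI on the OR scale for binary). Perfect separation is flagged by
    setting ``estimable = False`` on all rows rather than reporting a bogus
    estimate.
    """
    y = np.asarray(outcome, dtype=float)
    prot = np.asarray(predicted_age, dtype=float)
    chron = np.asarray(chronological_age, dtype=float)
    if family == "binary" and len(np.unique(y)) < 2:
        raise ValueError("binary outcome is degenerate (single level)")
    cols = {"proteomic_age": prot, "chronological_age": chron,
            "chronological_age_sq": chron**2}
    if sex is not None:
        cols["sex_male"] = (np.asarray(sex) == "male").astype(float)
    X = sm.add_constant(pd.DataFrame(cols))

    if family == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            except Exception as exc:  # separation or failure to converge
                logger.warning("logistic fit flagged: %s", exc)
                out = pd.DataFrame(
                    np.nan, index=X.columns.drop("const"),
                    columns=["effect", "lo", "hi", "p"],
                )
                out["estimable"] = False
                return out
        params, se = fit.params, fit.bse
        eff = np.exp(params)
        lo = np.exp(params - 1.96 * se)
        hi = np.exp(params + 1.96 * se)
    elif family == "continuous":
        fit = sm.OLS(y, X).fit()
        params, se = fit.params, fit.bse
        eff, lo, hi = params, params - 1.96 * se, params + 1.96 * se
    else:
        raise ValueError(f"unknown family {family!r}")

    out = pd.DataFrame(
        {"effect": eff, "lo": lo, "hi": hi, "p": fit.pvalues}
    ).drop(index="const")
    out["estimable"] = True
    return out


def fit_cox(
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
) -> SurvivalFit:
    """Cox proportional-hazards fit of survival on the given covariates.

    Raises on non-positive times, absence of events, or constant covariates
    (no contrast — the partial likelihood is flat). HRs and CIs follow
    HR = exp(beta), CI = exp(beta +/- 1.96 se).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if e.sum() < 1:
        raise ValueError("need at least one event")
    cov = covariates.reset_index(drop=True).astype(float)
    degenerate = cov.columns[cov.std(axis=0) == 0]
    if len(degenerate):
        raise ValueError(
            f"constant covariate(s) {list(degenerate)}: beta=0, se infinite"
        )
    df = cov.copy()
    df["time"], df["event"] = t, e
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    table = pd.DataFrame(
        {
            "beta": summ["coef"],
            "se": summ["se(coef)"],
            "hr": np.exp(summ["coef"]),
            "hr_lo": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "hr_hi": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "p": summ["p"],
        }
    )
    return SurvivalFit(
        table=table,
        baseline_cumhaz=cph.baseline_cumulative_hazard_,
        n=len(t),
        n_events=int(e.sum()),
        log_likelihood=float(cph.log_likelihood_),
        fitter=cph,
        data=df,
        duration_col="time",
        event_col="event",
    )


def schoenfeld_ph_test(fit: SurvivalFit, time_transform: str = "identity") -> pd.DataFrame:
    """Proportional-hazards test from scaled Schoenfeld residuals.

    Each covariate's scaled residuals are correlated with (transformed)
    event time and tested chi-square with 1 df; a global row sums the
    per-covariate chi-squares (df = number of covariates) as an omnibus
    approximation. The identity time transform is the default.
    """
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for the Schoenfeld test")
    res = proportional_hazard_test(
        fit.fitter, fit.data, time_transform=time_transform
    )
    summ = res.summary
    summ = summ.droplevel(1) if isinstance(summ.index, pd.MultiIndex) else summ
    out = pd.DataFrame(
        {"chi2": summ["test_statistic"], "p": summ["p"], "df": 1}
    )
    from scipy import stats as _st

    global_chi2 = float(out["chi2"].sum())
    global_df = len(out)
    out.loc["GLOBAL"] = [global_chi2, float(_st.chi2.sf(global_chi2, global_df)), global_df]
    return out


def km_estimate(
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier curves per group with Greenwood CIs, plus log-rank p.

    Returns a long table (group, time, survival, lo, hi) and the log-rank
    test p-value across groups.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    g = np.asarray(group_labels)
    frames = []
    for label in pd.unique(g):
        sel = g == label
        if sel.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(label))
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        frames.append(
            pd.DataFrame(
                {
                    "group": str(label),
                    "time": surv.index.to_numpy(),
                    "survival": surv.to_numpy(),
                    "lo": ci.iloc[:, 0].to_numpy(),
                    "hi": ci.iloc[:, 1].to_numpy(),
                }
            )
        )
    if len(frames) < 2:
        raise ValueError("need at least 2 groups")
    lr = multivariate_logrank_test(t, g, e)
    return pd.concat(frames, ignore_index=True), float(lr.p_value)


def top_decile_groups(
    predicted_age: np.ndarray | pd.Series,
    chronological_age: np.ndarray | pd.Series,
    frac: float = 0.10,
) -> np.ndarray:
    """Label the oldest `frac` of samples by age-adjusted proteomic age.

    Adjustment is OLS residualisation of predicted on chronological age;
    the top decile of residuals is labelled ``"oldest10"`` and the rest
    ``"rest"`` — the stratification used for the mortality curves.
    """
    yhat = np.asarray(predicted_age, dtype=float)
    age = np.asarray(chronological_age, dtype=float)
    X = sm.add_constant(age)
    resid = yhat - X @ sm.OLS(yhat, X).fit().params
    cut = np.quantile(resid, 1.0 - frac)
    return np.where(resid > cut, "oldest10", "rest")


def cox_score_test_at_zero(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> float:
    """Breslow score test statistic of a single covariate at beta = 0.

    U(0)^2 / I(0) with the usual risk-set sums; equals the log-rank
    chi-square for a binary covariate (exactly so when event times are
    distinct). Used as an independent cross-check of the Cox machinery.
    """
    order = np.argsort(time, kind="mergesort")
    t, e, z = time[order], event[order], x[order]
    u = 0.0
    info = 0.0
    for i in np.flatnonzero(e):
        at_risk = t >= t[i]
        s0 = at_risk.sum()
        s1 = z[at_risk].sum()
        s2 = (z[at_risk] ** 2).sum()
        u += z[i] - s1 / s0
        info += s2 / s0 - (s1 / s0) ** 2
    return float(u**2 / info)
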