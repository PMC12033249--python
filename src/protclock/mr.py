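"""Two-sample Mendelian randomisation: IVW and MR-Egger estimators.

Instruments arrive as per-SNP effect pairs (beta on the exposure, beta on
the outcome, with standard errors). After allele harmonisation and
orientation to positive exposure effects:

* **IVW** regresses outcome betas on exposure betas through the origin with
  weights 1/se_out^2. The slope algebraically equals the inverse-variance-
  weighted mean of per-instrument Wald ratios (beta_out/beta_exp weighted by
  beta_exp^2/se_out^2); that identity is asserted on every run as a
  self-check. Fixed-effect SE by default, with a multiplicative
  random-effects option inflating by the residual scale.
* **MR-Egger** adds an intercept — the directional-pleiotropy diagnostic —
  and inflates both SEs by max(1, residual scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MRResult", "harmonize", "ivw_estimate", "egger_estimate"]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MRResult:
    method: str  # "IVW" | "Egger"
    slope: float
    slope_se: float
    slope_p: float
    n_instruments: int
    q_statistic: float
    q_df: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "slope": self.slope, "slope_se": self.slope_se, "slope_p": self.slope_p,
            "intercept": self.intercept, "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
            "n_instruments": self.n_instruments,
            "q_statistic": self.q_statistic, "q_df": self.q_df,
        }


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def harmonize(mr_input: pd.DataFrame) -> pd.DataFrame:
    """Align alleles across exposure and outcome and orient instruments.

    Expected columns: SNP, EA, OA, beta_exp, se_exp, beta_out, se_out, and
    optionally EA_out/OA_out when the outcome study reports its own allele
    labels. Instruments whose outcome alleles are the flip of the exposure
    alleles get their outcome beta sign-flipped; strand flips (complement
    alleles) are aligned likewise; palindromic (A/T or C/G) instruments are
    dropped since strand cannot be resolved without frequencies;
    irreconcilable pairs are dropped with a log entry. Finally every
    instrument is oriented so beta_exp > 0 (flipping both betas), the
    orientation the Egger model needs.
    """
    df = mr_input.copy()
    required = {"SNP", "EA", "OA", "beta_exp", "se_exp", "beta_out", "se_out"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"MR input lacks columns: {sorted(missing)}")
    if (df["se_exp"] <= 0).any() or (df["se_out"] <= 0).any():
        raise ValueError("standard errors must be positive")

    keep = []
    for row in df.itertuples():
        ea, oa = row.EA.upper(), row.OA.upper()
        if _is_palindromic(ea, oa):
            logger.info("harmonize: dropping palindromic instrument %s (%s/%s)",
                        row.SNP, ea, oa)
            keep.append(False)
            continue
        if hasattr(row, "EA_out") and isinstance(row.EA_out, str):
            ea_o, oa_o = row.EA_out.upper(), row.OA_out.upper()
            flip = {_COMPLEMENT[ea_o], ea_o}, {_COMPLEMENT[oa_o], oa_o}
            if ea in flip[0] and oa in flip[1]:
                pass  # already aligned (same strand or complement)
            elif ea in flip[1] and oa in flip[0]:
                df.loc[row.Index, "beta_out"] = -row.beta_out
            else:
                logger.info("harmonize: dropping irreconcilable instrument %s", row.SNP)
                keep.append(False)
                continue
        keep.append(True)
    df = df.loc[np.asarray(keep, dtype=bool)].copy()

    neg = df["beta_exp"] < 0
    if neg.any():
        df.loc[neg, ["beta_exp", "beta_out"]] *= -1.0
        ea, oa = df.loc[neg, "EA"].copy(), df.loc[neg, "OA"].copy()
        df.loc[neg, "EA"], df.loc[neg, "OA"] = oa.to_numpy(), ea.to_numpy()
    return df.reset_index(drop=True)


def _q_statistic(bx, by, w, slope, intercept=0.0) -> float:
    return float((w * (by - intercept - slope * bx) ** 2).sum())


def ivw_estimate(
    mr_input: pd.DataFrame, random_effects: bool = False, min_instruments: int = 2
) -> MRResult:
    """Inverse-variance-weighted MR estimate (no-intercept WLS).

    With weights w_j = 1/se_out_j^2: slope = sum(w bx by) / sum(w bx^2),
    SE = sqrt(1 / sum(w bx^2)) (fixed effect), optionally inflated by the
    residual scale sqrt(Q/(k-1)) when it exceeds 1 (multiplicative random
    effects). Cochran's Q is reported with k-1 df. ``min_instruments`` can
    be lowered to 1, in which case the estimate is the single Wald ratio.
    """
    bx = mr_input["beta_exp"].to_numpy(dtype=float)
    by = mr_input["beta_out"].to_numpy(dtype=float)
    se = mr_input["se_out"].to_numpy(dtype=float)
    k = len(bx)
    if k < max(min_instruments, 1):
        raise InsufficientInstrumentsError("IVW needs >= 2 instruments")
    w = 1.0 / se**2
    denom = float((w * bx**2).sum())
    slope = float((w * bx * by).sum()) / denom
    se_slope = float(np.sqrt(1.0 / denom))

    # Self-check: the regression form must equal the weighted mean of Wald
    # ratios with weights bx^2/se^2 (exact algebra, not an approximation).
    ratios = by / bx
    wr = bx**2 / se**2
    wald_mean = float((wr * ratios).sum() / wr.sum())
    assert abs(slope - wald_mean) <= 1e-10 * max(1.0, abs(slope)), (
        "IVW identity violated"
    )

    q = _q_statistic(bx, by, w, slope)
    if random_effects:
        se_slope *= max(1.0, np.sqrt(q / (k - 1)))
    p = 2.0 * stats.norm.sf(abs(slope) / se_slope)
    return MRResult("IVW", slope, se_slope, float(p), k, q, k - 1)


def egger_estimate(mr_input: pd.DataFrame) -> MRResult:
    """MR-Egger: weighted regression with an intercept for pleiotropy.

    Requires >= 3 instruments oriented to beta_exp > 0 and non-identical
    exposure betas. Slope and intercept SEs are inflated by
    max(1, sqrt(Q/(k-2))) (multiplicative random effects); p-values use the
    t distribution with k-2 df. A significant intercept indicates
    directional pleiotropy.
    """
    bx = mr_input["beta_exp"].to_numpy(dtype=float)
    by = mr_input["beta_out"].to_numpy(dtype=float)
    se = mr_input["se_out"].to_numpy(dtype=float)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("Egger needs >= 3 instruments")
    if (bx < 0).any():
        raise ValueError("Egger requires beta_exp > 0 orientation; run harmonize first")
    if np.ptp(bx) == 0:
        raise ValueError("identical exposure betas: Egger slope unidentifiable")
    w = 1.0 / se**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    intercept, slope = float(coef[0]), float(coef[1])
    q = _q_statistic(bx, by, w, slope, intercept)
    scale = max(1.0, np.sqrt(q / (k - 2)))
    cov = np.linalg.inv(xtx) * scale**2
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    df = k - 2
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
    return MRResult(
        "Egger", slope, se_slope, float(p_slope), k, q, df,
        intercept=intercept, intercept_se=se_int, intercept_p=float(p_int),
    )
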