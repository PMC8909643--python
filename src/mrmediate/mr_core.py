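"""Univariable two-sample MR estimators and per-SNP diagnostics.

Implements the Wald ratio, fixed- and multiplicative-random-effects IVW,
MR-Egger regression (slope + intercept pleiotropy test), simple and weighted
median estimators with parametric-bootstrap standard errors, single-SNP and
leave-one-out analyses, and Cochran's Q heterogeneity statistic.

Conventions
-----------
* Wald-ratio SEs are first-order ("NOME"): exposure-side uncertainty is
  ignored, which is adequate for strong instruments (F > 10 enforced
  upstream).
* The default IVW model is multiplicative random effects: the fixed-effect
  SE is inflated by sqrt(max(1, Q/(J-1))), never deflated.
* IVW / median p-values come from the normal distribution; MR-Egger uses
  the t distribution with J-2 degrees of freedom (small-sample convention).
* MR-Egger is fit after orienting every SNP so that the exposure effect is
  nonnegative; the estimator is not orientation-invariant, so a fixed
  convention is required for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .sumstats import HarmonizedSet

__all__ = [
    "MrResult",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "simple_median",
    "weighted_median",
    "single_snp_analysis",
    "leave_one_out",
    "cochran_q",
]

Z95 = stats.norm.ppf(0.975)
_P_FLOOR = 1e-300


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


@dataclass
class MrResult:
    """One estimator's causal-effect estimate.

    ``beta`` is on the outcome scale per unit exposure (log-odds per
    log-odds for a binary exposure and outcome); ``or_`` = exp(beta) is the
    presentation-layer odds ratio.
    """

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    exposure: str = ""
    outcome: str = ""
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "Analysis": self.method,
            "Nsnp": self.nsnp,
            "Effect": self.beta,
            "Se": self.se,
            "P-value": self.pval,
            "OR": self.or_,
        }


def _norm_p(z: float) -> float:
    return max(float(2 * stats.norm.sf(abs(z))), _P_FLOOR)


def _t_p(t: float, df: int) -> float:
    return max(float(2 * stats.t.sf(abs(t), df)), _P_FLOOR)


def wald_ratio(bx: float, by: float, sy: float) -> tuple[float, float]:
    """Single-SNP causal estimate by/bx with first-order SE sy/|bx|."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    if sy <= 0:
        raise ValueError("sy must be positive")
    return by / bx, sy / abs(bx)


def cochran_q(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, beta: float
) -> tuple[float, int]:
    """Heterogeneity about a fitted slope: Q = sum((by - beta*bx)² / sy²)."""
    q = float(np.sum((by - beta * bx) ** 2 / sy**2))
    return q, len(by) - 1


def ivw(h: HarmonizedSet, model: str = "random") -> MrResult:
    """Inverse-variance-weighted estimate of the causal effect.

    beta = sum(bx*by/sy²) / sum(bx²/sy²) — the 1/sy²-weighted regression of
    by on bx through the origin, equivalently the bx²/sy²-weighted mean of
    the per-SNP Wald ratios. ``model="random"`` (default) inflates the SE by
    sqrt(max(1, Q/(J-1))) (multiplicative random effects).
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    bx, sx, by, sy = h.univariable()
    j = len(bx)
    if j == 1:
        ratio, se = wald_ratio(bx[0], by[0], sy[0])
        return MrResult(
            "wald", 1, ratio, se, _norm_p(ratio / se),
            exposure=h.exposure_names[0], outcome=h.outcome_name,
        )
    w_den = float(np.sum(bx**2 / sy**2))
    if w_den == 0:
        raise ValueError("all exposure effects are zero")
    beta = float(np.sum(bx * by / sy**2)) / w_den
    se_fixed = math.sqrt(1.0 / w_den)
    q, q_df = cochran_q(bx, by, sy, beta)
    se = se_fixed
    if model == "random":
        se = se_fixed * math.sqrt(max(1.0, q / q_df))
    return MrResult(
        method=f"ivw_{model}",
        nsnp=j,
        beta=beta,
        se=se,
        pval=_norm_p(beta / se),
        exposure=h.exposure_names[0],
        outcome=h.outcome_name,
        q_stat=q,
        q_df=q_df,
        q_p=max(float(stats.chi2.sf(q, q_df)), _P_FLOOR),
    )


def mr_egger(h: HarmonizedSet) -> MrResult:
    """MR-Egger: 1/sy²-weighted regression of by on bx with an intercept.

    The intercept estimates the average directional-pleiotropy effect; its
    t test (J-2 df) is the Egger pleiotropy test. SEs carry a multiplicative
    dispersion factor max(1, RSS/(J-2)).
    """
    bx, sx, by, sy = h.univariable()
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 SNPs")
    flip = np.where(bx < 0, -1.0, 1.0)  # orientation convention: bx >= 0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise ValueError("zero variance in exposure effects: singular Egger fit")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    # dispersion floored at 1 (never deflate below the fixed-effect SE),
    # computed from the unscaled covariance so exact fits stay finite
    scale = max(1.0, fit.scale)
    (a, beta) = fit.params
    (se_a, se_b) = np.sqrt(np.diag(fit.normalized_cov_params) * scale)
    q = float(fit.ssr)  # weighted RSS about the Egger line
    return MrResult(
        method="egger",
        nsnp=j,
        beta=float(beta),
        se=float(se_b),
        pval=_t_p(beta / se_b, j - 2),
        exposure=h.exposure_names[0],
        outcome=h.outcome_name,
        egger_intercept=float(a),
        egger_intercept_se=float(se_a),
        egger_intercept_p=_t_p(a / se_a, j - 2),
        q_stat=q,
        q_df=j - 2,
        q_p=max(float(stats.chi2.sf(q, j - 2)), _P_FLOOR),
    )


def _interp_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def _median_estimate(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, weighted: bool
) -> float:
    ratios = by / bx
    weights = bx**2 / sy**2 if weighted else np.ones_like(ratios)
    return _interp_median(ratios, weights)


def _median_mr(
    h: HarmonizedSet, weighted: bool, n_boot: int, seed: int
) -> MrResult:
    bx, sx, by, sy = h.univariable()
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("median estimators require at least 3 SNPs")
    if (bx == 0).any():
        raise ZeroDivisionError("median estimators require nonzero exposure effects")
    est = _median_estimate(bx, by, sy, weighted)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        bx_i = rng.normal(bx, sx)
        by_i = rng.normal(by, sy)
        boot[i] = _median_estimate(np.where(bx_i == 0, 1e-300, bx_i), by_i, sy, weighted)
    se = float(np.std(boot, ddof=1))
    p = _norm_p(est / se) if se > 0 else _P_FLOOR
    return MrResult(
        method="weighted_median" if weighted else "simple_median",
        nsnp=j, beta=est, se=se, pval=p,
        exposure=h.exposure_names[0], outcome=h.outcome_name,
    )


def simple_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Unweighted median of per-SNP Wald ratios; SE by parametric bootstrap."""
    return _median_mr(h, weighted=False, n_boot=n_boot, seed=seed)


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Inverse-variance weighted median of Wald ratios (consistent when <50%
    of the weight lies on invalid instruments); SE by parametric bootstrap."""
    return _median_mr(h, weighted=True, n_boot=n_boot, seed=seed)


def single_snp_analysis(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios. SNPs with bx = 0 are excluded with a reason."""
    bx, sx, by, sy = h.univariable()
    rows = []
    for i, snp in enumerate(h.snp_ids):
        if bx[i] == 0:
            rows.append({"snp_id": snp, "ratio": np.nan, "ratio_se": np.nan,
                         "note": "undefined: bx = 0"})
            continue
        ratio, se = wald_ratio(bx[i], by[i], sy[i])
        rows.append({"snp_id": snp, "ratio": ratio, "ratio_se": se, "note": ""})
    return pd.DataFrame(rows)


def leave_one_out(h: HarmonizedSet, model: str = "random") -> pd.DataFrame:
    """IVW re-estimated J times, each time excluding one SNP."""
    if h.n_snps < 3:
        raise InsufficientInstrumentsError("leave-one-out requires at least 3 SNPs")
    rows = []
    for snp in h.snp_ids:
        res = ivw(h.drop_snps([snp], reason="left out"), model=model)
        rows.append({"left_out_snp": snp, "beta": res.beta, "se": res.se,
                     "pval": res.pval})
    return pd.DataFrame(rows)
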