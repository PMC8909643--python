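"""Regression-based multivariable MR.

Jointly regresses SNP-outcome effects on the J x K matrix of SNP-exposure
effects (no intercept, weights 1/sy²) to obtain each exposure's direct
effect on the outcome conditional on the others. With K = 1 this reduces
exactly to the fixed-effect univariable IVW estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .instruments import WEAK_INSTRUMENT_F
from .mr_core import InsufficientInstrumentsError, _P_FLOOR
from .sumstats import HarmonizedSet

__all__ = ["MvmrResult", "CollinearityError", "mvmr_ivw"]


class CollinearityError(ValueError):
    """The exposure design matrix is rank-deficient."""


@dataclass
class MvmrResult:
    exposure_names: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    nsnp: int
    outcome: str = ""
    conditioning_note: str = ""
    weak_exposures: list[str] = field(default_factory=list)

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.betas)

    def row(self, exposure: str) -> dict:
        i = self.exposure_names.index(exposure)
        return {
            "exposure": exposure,
            "beta": float(self.betas[i]),
            "se": float(self.ses[i]),
            "pval": float(self.pvals[i]),
            "or": float(self.or_[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.row(e) for e in self.exposure_names]).assign(
            outcome=self.outcome, nsnp=self.nsnp
        )


def mvmr_ivw(h: HarmonizedSet) -> MvmrResult:
    """Weighted least squares of by on the exposure-effect matrix.

    Requires more SNPs than exposures (J > K) and a full-rank design.
    SEs carry the multiplicative dispersion factor max(1, RSS/(J-K)) and
    p-values are two-sided normal, matching the univariable conventions.
    """
    X = h.bx.T  # J x K
    j, k = X.shape
    if j <= k:
        raise InsufficientInstrumentsError(
            f"inadequate SNPs: J={j} instruments for K={k} exposures"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the exposures involved in the deficiency for the error message
        culprits = [
            name
            for i, name in enumerate(h.exposure_names)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise CollinearityError(
            "rank-deficient exposure design; collinear or degenerate exposure(s): "
            + ", ".join(culprits or h.exposure_names)
        )
    fit = sm.WLS(h.by, X, weights=1.0 / h.sy**2).fit()
    # dispersion floored at 1; unscaled covariance keeps exact fits finite
    ses = np.sqrt(np.diag(fit.normalized_cov_params) * max(1.0, fit.scale))
    z = np.asarray(fit.params) / ses
    pvals = np.maximum(2 * stats.norm.sf(np.abs(z)), _P_FLOOR)

    weak = [
        name
        for i, name in enumerate(h.exposure_names)
        if float(np.min((h.bx[i] / h.sx[i]) ** 2)) <= WEAK_INSTRUMENT_F
    ]
    return MvmrResult(
        exposure_names=list(h.exposure_names),
        betas=np.asarray(fit.params, dtype=float),
        ses=ses.astype(float),
        pvals=pvals.astype(float),
        nsnp=j,
        outcome=h.outcome_name,
        conditioning_note="adjusted for: " + ", ".join(h.exposure_names),
        weak_exposures=weak,
    )
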