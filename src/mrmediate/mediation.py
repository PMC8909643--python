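"""Two-step mediation calculus with Gaussian (delta-method) error propagation.

The indirect effect of a mediator is the product of the step-1 effect
(exposure -> mediator, ``a``) and the step-2 direct effect (mediator ->
outcome adjusted for the exposure, ``b``). The proportion mediated divides
the indirect effect by the total effect. Combined mediation across all
mediators uses the difference method: total minus the exposure's direct
effect adjusted for every mediator.

Standard errors follow first-order propagation for independent Gaussian
errors:

* product:   se(ab)  = sqrt(a² se_b² + b² se_a²)
* quotient:  se(a/b) = |a/b| sqrt((se_a/a)² + (se_b/b)²)
* sum:       se(a±b) = sqrt(se_a² + se_b²)

Independence of the propagated terms is assumed (two-sample setting with
estimates from non-overlapping datasets); shared-instrument covariance
between the indirect and total effects is neglected — a documented
limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .mr_core import MrResult, Z95, _P_FLOOR
from .mvmr import MvmrResult

__all__ = [
    "MediationResult",
    "CombinedMediation",
    "se_product",
    "se_quotient",
    "se_sum",
    "indirect_effect",
    "proportion_mediated",
    "combined_mediation",
    "mediate",
]


def se_product(a: float, se_a: float, b: float, se_b: float) -> float:
    """First-order SE of a*b for independent Gaussian errors."""
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    return math.sqrt(a**2 * se_b**2 + b**2 * se_a**2)


def se_quotient(num: float, se_num: float, den: float, se_den: float) -> float:
    """First-order SE of num/den; at num = 0 the limit se_num/|den| applies."""
    if den == 0:
        raise ZeroDivisionError("quotient SE undefined for zero denominator")
    if num == 0:
        return se_num / abs(den)
    return abs(num / den) * math.sqrt((se_num / num) ** 2 + (se_den / den) ** 2)


def se_sum(se_1: float, se_2: float) -> float:
    """SE of a sum or difference of independent terms."""
    if se_1 < 0 or se_2 < 0:
        raise ValueError("standard errors must be nonnegative")
    return math.hypot(se_1, se_2)


def _z_p(est: float, se: float) -> float:
    if se == 0:
        return 1.0 if est == 0 else _P_FLOOR
    return max(float(2 * stats.norm.sf(abs(est / se))), _P_FLOOR)


@dataclass
class MediationResult:
    """Per-mediator two-step mediation summary.

    ``a`` is in mediator SD per unit exposure (log-odds for a binary
    exposure); ``b`` in outcome log-odds per mediator SD; ``indirect`` and
    ``total`` therefore share the outcome log-odds-per-exposure-unit scale.
    """

    mediator_name: str
    a: float
    se_a: float
    b: float
    se_b: float
    total: float
    se_total: float
    indirect: float
    se_indirect: float
    indirect_p: float
    proportion: float
    se_proportion: float
    ci_low: float
    ci_high: float
    flag: str = "ok"  # ok | excluded_step1 | excluded_step2 | inconsistent

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_row(self) -> dict:
        return {
            "mediator": self.mediator_name,
            "a": self.a, "se_a": self.se_a,
            "b": self.b, "se_b": self.se_b,
            "indirect": self.indirect, "se_indirect": self.se_indirect,
            "total": self.total,
            "proportion": self.proportion,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "flag": self.flag,
        }


@dataclass
class CombinedMediation:
    """Difference-method mediation through all mediators jointly."""

    total: float
    se_total: float
    direct_adjusted: float
    se_direct: float
    combined_indirect: float
    se_indirect: float
    combined_proportion: float
    se_proportion: float
    ci_low: float
    ci_high: float


def indirect_effect(
    a: float, se_a: float, b: float, se_b: float
) -> tuple[float, float, float]:
    """Product-method indirect effect: (a*b, delta-method SE, z-test p)."""
    est = a * b
    se = se_product(a, se_a, b, se_b)
    return est, se, _z_p(est, se)


def proportion_mediated(
    indirect: float, se_indirect: float, total: float, se_total: float
) -> tuple[float, float, tuple[float, float]]:
    """Indirect/total with quotient SE and 95% CI (on the fraction scale)."""
    if total == 0:
        raise ZeroDivisionError("proportion mediated undefined for zero total effect")
    prop = indirect / total
    se = se_quotient(indirect, se_indirect, total, se_total)
    return prop, se, (prop - Z95 * se, prop + Z95 * se)


def combined_mediation(
    total: float, se_total: float, direct_adjusted: float, se_direct: float
) -> CombinedMediation:
    """Difference-method combined mediation across all mediators."""
    if total == 0:
        raise ZeroDivisionError("combined mediation undefined for zero total effect")
    indirect = total - direct_adjusted
    se_ind = se_sum(se_total, se_direct)
    prop, se_prop, (lo, hi) = proportion_mediated(indirect, se_ind, total, se_total)
    return CombinedMediation(
        total=total, se_total=se_total,
        direct_adjusted=direct_adjusted, se_direct=se_direct,
        combined_indirect=indirect, se_indirect=se_ind,
        combined_proportion=prop, se_proportion=se_prop,
        ci_low=lo, ci_high=hi,
    )


def mediate(
    step1: MrResult,
    step2: MvmrResult,
    total: MrResult,
    mediator_name: str | None = None,
    flag: str = "ok",
) -> MediationResult:
    """Assemble a per-mediator MediationResult from fitted pieces.

    ``step1`` is the univariable MR of exposure on the mediator; ``step2``
    the MVMR whose ``mediator_name`` row gives the mediator's direct effect
    on the outcome; ``total`` the univariable MR of exposure on the outcome.
    """
    name = mediator_name or step1.outcome
    row = step2.row(name)
    a, se_a = step1.beta, step1.se
    b, se_b = row["beta"], row["se"]
    ind, se_ind, p = indirect_effect(a, se_a, b, se_b)
    prop, se_prop, (lo, hi) = proportion_mediated(ind, se_ind, total.beta, total.se)
    if abs(prop) > 1 and flag == "ok":
        flag = "inconsistent"
    return MediationResult(
        mediator_name=name,
        a=a, se_a=se_a, b=b, se_b=se_b,
        total=total.beta, se_total=total.se,
        indirect=ind, se_indirect=se_ind, indirect_p=p,
        proportion=prop, se_proportion=se_prop,
        ci_low=lo, ci_high=hi,
        flag=flag,
    )
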