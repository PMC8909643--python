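"""Desk-scale worked example: published consortium point estimates.

The fixture transcribes the point estimates (with 95% CIs) from a published
consortium-scale two-step MR study of type 2 diabetes (T2DM) and
cardiovascular disease: the step-1 effects of T2DM on systolic blood
pressure (SBP), diastolic blood pressure (DBP) and triglycerides (TG) in SD
per log-odds; the multivariable-MR odds ratios of each CVD subtype per SD
of mediator, adjusted for T2DM; and the total-effect odds ratios of T2DM on
coronary heart disease (CHD), myocardial infarction (MI) and stroke.

``worked_example_report`` recomputes every product-method mediation
proportion from these inputs and lays the computed percentages beside the
published ones; residual discrepancies reflect only the rounding of the
published inputs.
"""

from __future__ import annotations

import math

import pandas as pd

from .mediation import indirect_effect, proportion_mediated

__all__ = [
    "STEP1_BETA",
    "STEP2_OR",
    "TOTAL_OR",
    "PUBLISHED_PCT",
    "se_from_ci",
    "se_from_or_ci",
    "worked_example_report",
]

#: exposure -> mediator effects, SD per unit log-odds: (beta, (ci_low, ci_high))
STEP1_BETA = {
    "SBP": (0.77, (0.49, 1.04)),
    "DBP": (0.22, (0.06, 0.38)),
    "TG": (0.08, (0.02, 0.14)),
}

#: mediator -> outcome odds ratios per SD, adjusted for the exposure
STEP2_OR = {
    "CHD": {
        "SBP": (1.03, (1.02, 1.04)),
        "DBP": (1.05, (1.04, 1.06)),
        "TG": (1.22, (1.13, 1.32)),
    },
    "MI": {
        "SBP": (1.03, (1.02, 1.03)),
        "DBP": (1.05, (1.04, 1.06)),
        "TG": (1.22, (1.12, 1.33)),
    },
    "stroke": {
        "SBP": (1.03, (1.03, 1.04)),
        "DBP": (1.04, (1.04, 1.05)),
        "TG": (1.00, (0.95, 1.06)),
    },
}

#: total-effect odds ratios of the exposure on each outcome
TOTAL_OR = {
    "CHD": (1.16, (1.12, 1.21)),
    "MI": (1.15, (1.10, 1.20)),
    "stroke": (1.10, (1.06, 1.13)),
}

#: published proportions mediated, in percent
PUBLISHED_PCT = {
    "CHD": {"SBP": 16.0, "DBP": 7.0, "TG": 10.0},
    "MI": {"SBP": 14.0, "DBP": 7.0, "TG": 11.0},
    "stroke": {"SBP": 26.0, "DBP": 10.0, "TG": 0.4},
}

_Z95 = 1.959963984540054


def se_from_ci(lo: float, hi: float) -> float:
    """SE implied by a symmetric 95% CI on an additive scale."""
    return (hi - lo) / (2 * _Z95)


def se_from_or_ci(lo: float, hi: float) -> float:
    """SE of the log odds ratio implied by a 95% CI on the OR scale."""
    return (math.log(hi) - math.log(lo)) / (2 * _Z95)


def mediation_proportion_pct(outcome: str, mediator: str) -> float:
    """Product-method proportion mediated (percent) from the fixture inputs."""
    a, (alo, ahi) = STEP1_BETA[mediator]
    or2, (blo, bhi) = STEP2_OR[outcome][mediator]
    ort, (tlo, thi) = TOTAL_OR[outcome]
    b = math.log(or2)
    total = math.log(ort)
    ind, se_ind, _ = indirect_effect(a, se_from_ci(alo, ahi), b, se_from_or_ci(blo, bhi))
    prop, _, _ = proportion_mediated(ind, se_ind, total, se_from_or_ci(tlo, thi))
    return 100.0 * prop


def worked_example_report() -> pd.DataFrame:
    """Computed vs published mediation percentages for every pair."""
    rows = []
    for outcome, meds in STEP2_OR.items():
        for mediator in meds:
            a, (alo, ahi) = STEP1_BETA[mediator]
            or2, (blo, bhi) = STEP2_OR[outcome][mediator]
            ort, (tlo, thi) = TOTAL_OR[outcome]
            b, total = math.log(or2), math.log(ort)
            se_a = se_from_ci(alo, ahi)
            se_b = se_from_or_ci(blo, bhi)
            se_t = se_from_or_ci(tlo, thi)
            ind, se_ind, p = indirect_effect(a, se_a, b, se_b)
            prop, se_p, (lo, hi) = proportion_mediated(ind, se_ind, total, se_t)
            rows.append(
                {
                    "outcome": outcome,
                    "mediator": mediator,
                    "a": a,
                    "b_log_or": b,
                    "total_log_or": total,
                    "indirect": ind,
                    "se_indirect": se_ind,
                    "computed_pct": 100 * prop,
                    "ci_low_pct": 100 * lo,
                    "ci_high_pct": 100 * hi,
                    "published_pct": PUBLISHED_PCT[outcome][mediator],
                }
            )
    return pd.DataFrame(rows)
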