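"""Synthetic two-sample GWAS summary statistics under a known mediation model.

The generative structural model is exposure -> mediator(s) -> outcome with an
additional direct exposure -> outcome path:

* exposure instruments j carry true exposure effects gamma_j ~ |N(0, gamma_sd²)|
  (effect alleles are coded in the exposure-increasing direction, as GWAS lead
  SNPs conventionally are; directional pleiotropy is therefore expressed in a
  fixed orientation and recoverable by the Egger intercept);
* each mediator has its own instruments kappa ~ |N(0, kappa_sd²)|, giving the
  multivariable design full column rank;
* the true mediator effect of an exposure SNP is alpha * gamma_j; of the
  mediator's own SNP, kappa;
* the true outcome effect of an exposure SNP is
  gamma_j * (beta_d + sum_m alpha_m * beta_m) + theta_j, where theta_j ~
  N(pleiotropy_mean, pleiotropy_sd²) for the invalid fraction of instruments
  (horizontal pleiotropy) and 0 otherwise; a mediator SNP contributes
  kappa * beta_m;
* observed effects add N(0, se²) sampling noise per trait, with the se scale
  reported as the standard error (summary-level two-sample setting; SEs play
  the role of 1/sqrt(n)).

Each trait's table covers the union of all instruments, so downstream
harmonization and instrument selection run exactly as they would on real
summary statistics. Alleles are fixed to A/G (non-palindromic) and the LD
matrix is the identity: instruments are simulated independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .instruments import LdMatrix
from .sumstats import SummaryTable, VariantAssociation

__all__ = [
    "MediationTruth",
    "MediatorSpec",
    "TruthSummary",
    "truth_summary",
    "simulate_mediation_sumstats",
    "simulate_study",
]

_P_FLOOR = 1e-300


@dataclass
class MediationTruth:
    """Generative parameters for a single-mediator mediation study.

    Defaults emulate a consortium-scale study: 143 exposure instruments
    with typical instrument F around 25-100 (gamma_sd / se_x), moderate
    mediation (proportion mediated 2/3), and no horizontal pleiotropy.
    """

    j_exposure: int = 143
    j_mediator: int = 50
    gamma_sd: float = 0.08
    alpha: float = 0.5
    beta_m: float = 0.4
    beta_d: float = 0.1
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    se_x: float = 0.01
    se_m: float = 0.005
    se_y: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_exposure < 1 or self.j_mediator < 1:
            raise ValueError("instrument counts must be >= 1")
        if min(self.gamma_sd, self.pleiotropy_sd) < 0:
            raise ValueError("scale parameters must be nonnegative")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must lie in [0,1]")
        if min(self.se_x, self.se_m, self.se_y) <= 0:
            raise ValueError("se scales must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MediatorSpec:
    """One mediator's role in a multi-mediator study."""

    name: str
    alpha: float
    beta_m: float
    n_instruments: int = 50
    kappa_sd: float = 0.08


@dataclass
class TruthSummary:
    total_effect: float
    indirect: float
    proportion: float | None


def truth_summary(truth: MediationTruth) -> TruthSummary:
    """Closed-form targets implied by the generative parameters."""
    indirect = truth.alpha * truth.beta_m
    total = truth.beta_d + indirect
    prop = indirect / total if total != 0 else None
    return TruthSummary(total_effect=total, indirect=indirect, proportion=prop)


def _observe(
    rng: np.random.Generator,
    snp_ids: list[str],
    true_beta: np.ndarray,
    se: float,
    eaf: np.ndarray,
    trait_name: str,
    trait_type: str,
) -> SummaryTable:
    beta = rng.normal(true_beta, se)
    z = beta / se
    pval = np.maximum(2 * stats.norm.sf(np.abs(z)), _P_FLOOR)
    n = int(round(1.0 / se**2))
    records = [
        VariantAssociation(
            snp_id=s,
            effect_allele="A",
            other_allele="G",
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=se,
            pval=float(pval[i]),
            n=n,
        )
        for i, s in enumerate(snp_ids)
    ]
    return SummaryTable(trait_name, trait_type, records)


def simulate_study(
    mediators: list[MediatorSpec],
    beta_d: float,
    j_exposure: int = 143,
    gamma_sd: float = 0.08,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    invalid_fraction: float = 0.0,
    se_x: float = 0.01,
    se_m: float = 0.005,
    se_y: float = 0.02,
    seed: int = 0,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> tuple[SummaryTable, dict[str, SummaryTable], SummaryTable, LdMatrix]:
    """Simulate one exposure, several mediators and one outcome.

    Returns (exposure table, {mediator name: table}, outcome table, LD).
    """
    rng = np.random.default_rng(seed)
    exp_ids = [f"rs{i + 1}" for i in range(j_exposure)]
    gamma = np.abs(rng.normal(0.0, gamma_sd, j_exposure))

    med_ids: dict[str, list[str]] = {}
    kappa: dict[str, np.ndarray] = {}
    offset = j_exposure
    for spec in mediators:
        med_ids[spec.name] = [f"rs{offset + i + 1}" for i in range(spec.n_instruments)]
        kappa[spec.name] = np.abs(rng.normal(0.0, spec.kappa_sd, spec.n_instruments))
        offset += spec.n_instruments

    all_ids = exp_ids + [s for spec in mediators for s in med_ids[spec.name]]
    j_total = len(all_ids)
    eaf = rng.uniform(0.05, 0.95, j_total)

    # horizontal pleiotropy on a subset of the exposure instruments
    theta = np.zeros(j_exposure)
    n_invalid = int(round(invalid_fraction * j_exposure))
    if n_invalid:
        invalid = rng.choice(j_exposure, size=n_invalid, replace=False)
        theta[invalid] = rng.normal(pleiotropy_mean, pleiotropy_sd, n_invalid)

    total_slope = beta_d + sum(m.alpha * m.beta_m for m in mediators)

    true_x = np.concatenate([gamma, np.zeros(j_total - j_exposure)])
    true_y = np.zeros(j_total)
    true_y[:j_exposure] = gamma * total_slope + theta
    true_med = {m.name: np.zeros(j_total) for m in mediators}
    pos = j_exposure
    for spec in mediators:
        true_med[spec.name][:j_exposure] = spec.alpha * gamma
        true_med[spec.name][pos : pos + spec.n_instruments] = kappa[spec.name]
        true_y[pos : pos + spec.n_instruments] = kappa[spec.name] * spec.beta_m
        pos += spec.n_instruments

    exposure = _observe(rng, all_ids, true_x, se_x, eaf, exposure_name, "binary")
    mediator_tables = {
        m.name: _observe(rng, all_ids, true_med[m.name], se_m, eaf, m.name, "continuous")
        for m in mediators
    }
    outcome = _observe(rng, all_ids, true_y, se_y, eaf, outcome_name, "binary")
    return exposure, mediator_tables, outcome, LdMatrix.identity(all_ids)


def simulate_mediation_sumstats(
    truth: MediationTruth,
) -> tuple[SummaryTable, SummaryTable, SummaryTable, LdMatrix]:
    """Single-mediator study drawn from ``truth``; deterministic in the seed."""
    exposure, mediators, outcome, ld = simulate_study(
        mediators=[
            MediatorSpec(
                name="mediator",
                alpha=truth.alpha,
                beta_m=truth.beta_m,
                n_instruments=truth.j_mediator,
                kappa_sd=truth.gamma_sd,
            )
        ],
        beta_d=truth.beta_d,
        j_exposure=truth.j_exposure,
        gamma_sd=truth.gamma_sd,
        pleiotropy_mean=truth.pleiotropy_mean,
        pleiotropy_sd=truth.pleiotropy_sd,
        invalid_fraction=truth.invalid_fraction,
        se_x=truth.se_x,
        se_m=truth.se_m,
        se_y=truth.se_y,
        seed=truth.seed,
    )
    return exposure, mediators["mediator"], outcome, ld
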