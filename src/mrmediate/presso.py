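"""MR-PRESSO: simulation-based pleiotropy residual sum and outlier tests.

Three components, run in sequence:

* **global test** — observed residual sum of squares about leave-one-out IVW
  fits, compared with a parametric simulated null;
* **outlier test** — per-SNP squared residual against its simulated
  distribution, Bonferroni-adjusted across SNPs;
* **distortion test** — does removing the flagged outliers materially change
  the IVW estimate? The null distribution is built by replacing the outlier
  rows with bootstrap resamples of the inlier rows.

All randomness flows through one seeded generator, so results with the same
inputs and seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mr_core import InsufficientInstrumentsError, MrResult, ivw
from .sumstats import HarmonizedSet

__all__ = ["PressoResult", "presso_global", "presso_outlier", "presso_distortion",
           "run_presso"]

MIN_NSIM = 100


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    nsim: int
    seed: int
    outliers: list[tuple[str, float]] = field(default_factory=list)
    corrected: MrResult | None = None
    distortion_stat: float | None = None
    distortion_p: float | None = None


def _loo_betas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW point estimates, one per SNP (vectorized)."""
    w = 1.0 / sy**2
    num, den = np.sum(w * bx * by), np.sum(w * bx**2)
    return (num - w * bx * by) / (den - w * bx**2)


def _arrays(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bx, _, by, sy = h.univariable()
    return bx, by, sy


def _check(h: HarmonizedSet, nsim: int) -> None:
    if h.n_snps < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 SNPs")
    if nsim < MIN_NSIM:
        raise ValueError(f"nsim must be at least {MIN_NSIM}")


def _simulate_rss(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, nsim: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Null draws by* ~ N(loo_beta * bx, sy²); returns per-sim RSS and the
    per-sim per-SNP squared residuals (nsim x J)."""
    loo = _loo_betas(bx, by, sy)
    expected = loo * bx
    w = 1.0 / sy**2
    num, den = w * bx * by, w * bx**2
    s_num, s_den = num.sum(), den.sum()

    by_sim = rng.normal(expected, sy, size=(nsim, len(bx)))
    num_sim = w * bx * by_sim
    loo_sim = (num_sim.sum(axis=1, keepdims=True) - num_sim) / (s_den - den)
    res2 = (by_sim - loo_sim * bx) ** 2 * w
    return res2.sum(axis=1), res2


def presso_global(
    h: HarmonizedSet, nsim: int = 1000, seed: int = 0
) -> PressoResult:
    """Global heterogeneity test with empirical (add-one smoothed) p-value."""
    _check(h, nsim)
    bx, by, sy = _arrays(h)
    loo = _loo_betas(bx, by, sy)
    rss_obs = float(np.sum((by - loo * bx) ** 2 / sy**2))
    rng = np.random.default_rng(seed)
    rss_sim, _ = _simulate_rss(bx, by, sy, nsim, rng)
    p = (1 + int(np.sum(rss_sim >= rss_obs))) / (nsim + 1)
    return PressoResult(global_rss=rss_obs, global_p=p, nsim=nsim, seed=seed)


def presso_outlier(
    h: HarmonizedSet, nsim: int = 1000, seed: int = 0, alpha: float = 0.05
) -> list[tuple[str, float]]:
    """Per-SNP outlier test; returns (snp_id, Bonferroni-adjusted p) for SNPs
    whose adjusted p falls below ``alpha``."""
    _check(h, nsim)
    bx, by, sy = _arrays(h)
    loo = _loo_betas(bx, by, sy)
    obs = (by - loo * bx) ** 2 / sy**2
    rng = np.random.default_rng(seed)
    _, res2_sim = _simulate_rss(bx, by, sy, nsim, rng)
    p_raw = np.mean(res2_sim >= obs, axis=0)
    p_adj = np.minimum(1.0, p_raw * h.n_snps)
    return [
        (snp, float(p_adj[i]))
        for i, snp in enumerate(h.snp_ids)
        if p_adj[i] < alpha
    ]


def presso_distortion(
    h: HarmonizedSet,
    outliers: list[str],
    nsim: int = 1000,
    seed: int = 0,
    model: str = "random",
) -> tuple[MrResult, float, float]:
    """Distortion test: (corrected IVW, distortion statistic, empirical p).

    The statistic is (beta_all - beta_corrected) / beta_corrected. Its null
    distribution replaces the outlier rows with bootstrap copies of inlier
    rows, re-estimating each time.
    """
    out_set = set(outliers)
    if not out_set:
        raise ValueError("distortion test requires at least one flagged outlier")
    inlier_idx = [i for i, s in enumerate(h.snp_ids) if s not in out_set]
    if len(inlier_idx) < 2:
        raise InsufficientInstrumentsError(
            "fewer than 2 SNPs remain after outlier removal"
        )
    bx, by, sy = _arrays(h)
    beta_all = ivw(h, model=model).beta
    corrected = ivw(h.drop_snps(outliers, reason="presso outlier"), model=model)
    if corrected.beta == 0:
        raise ZeroDivisionError("corrected estimate is zero; distortion undefined")
    d_obs = (beta_all - corrected.beta) / corrected.beta

    def _ivw_point(ix: np.ndarray) -> float:
        w = 1.0 / sy[ix] ** 2
        return float(np.sum(w * bx[ix] * by[ix]) / np.sum(w * bx[ix] ** 2))

    rng = np.random.default_rng(seed)
    inliers = np.array(inlier_idx)
    n_out = len(out_set)
    count = 0
    for _ in range(nsim):
        fill = rng.choice(inliers, size=n_out, replace=True)
        beta_sim = _ivw_point(np.concatenate([inliers, fill]))
        d_sim = (beta_sim - corrected.beta) / corrected.beta
        if abs(d_sim) >= abs(d_obs):
            count += 1
    p = (1 + count) / (nsim + 1)
    return corrected, float(d_obs), p


def run_presso(
    h: HarmonizedSet,
    nsim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    model: str = "random",
) -> PressoResult:
    """Global test, then (if significant) outlier and distortion tests."""
    result = presso_global(h, nsim=nsim, seed=seed)
    if result.global_p >= alpha:
        return result
    result.outliers = presso_outlier(h, nsim=nsim, seed=seed, alpha=alpha)
    if result.outliers and len(result.outliers) < h.n_snps - 1:
        corrected, d, p = presso_distortion(
            h, [s for s, _ in result.outliers], nsim=nsim, seed=seed, model=model
        )
        result.corrected = corrected
        result.distortion_stat = d
        result.distortion_p = p
    return result
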