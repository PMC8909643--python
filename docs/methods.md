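# Methods

## Setting and model

`mrmediate` implements two-step, two-sample Mendelian randomization (MR)
mediation analysis on GWAS summary statistics. The causal diagram is

```
            alpha            beta_M
  exposure ───────► mediator ───────► outcome
      │                                  ▲
      └──────────────────────────────────┘
                     beta_D
```

For each genetic instrument *j* the inputs are the estimated SNP-exposure
effect `bx_j` (SE `sx_j`) and SNP-outcome effect `by_j` (SE `sy_j`), taken
from non-overlapping samples. Binary-trait effects are carried on the
natural-log-odds scale throughout; odds ratios are `exp(beta)` at the
presentation layer only. Continuous traits are in SD units.

The total effect decomposes as `beta_total = beta_D + alpha * beta_M`
(linearity, no exposure-mediator interaction). The **product method**
estimates the indirect effect as `a·b`, where `a` is the univariable MR
estimate of exposure→mediator and `b` is the mediator's direct effect on
the outcome from multivariable MR (MVMR) adjusting for the exposure. The
**difference method** estimates the combined indirect effect of all
mediators as `beta_total − beta_direct|all mediators`. The proportion
mediated is `indirect / total`.

## Estimators

* **Wald ratio** `by/bx`, SE `sy/|bx|`. First-order ("NOME"): exposure-side
  uncertainty is ignored, adequate for strong instruments (F > 10 is
  enforced upstream; the generator's defaults give typical F of 25–100).
* **IVW**: `beta = Σ bx·by/sy² / Σ bx²/sy²`, the 1/sy²-weighted regression
  of `by` on `bx` through the origin, algebraically the `bx²/sy²`-weighted
  mean of Wald ratios. Fixed-effect SE `sqrt(1/Σ bx²/sy²)`; the default
  multiplicative random-effects model inflates it by `sqrt(max(1, Q/(J−1)))`
  with Cochran's `Q = Σ (by − beta·bx)²/sy²`. The `max(1,·)` floor means
  random effects is never anti-conservative relative to fixed. p-values are
  two-sided normal.
* **MR-Egger**: 1/sy²-weighted regression of `by` on `bx` *with* intercept,
  after orienting all SNPs to `bx ≥ 0` (the estimator is not
  orientation-invariant; a fixed convention is required for
  reproducibility). The intercept estimates average directional pleiotropy;
  slope and intercept use t inference with J−2 df and the dispersion floor
  `max(1, RSS/(J−2))`.
* **Simple / weighted median** of the per-SNP ratios, with weights uniform
  or `bx²/sy²`, evaluated by linear interpolation of the cumulative
  standardized weight at 0.5. SEs by seeded parametric bootstrap
  (default 1000 draws of `bx* ~ N(bx, sx²)`, `by* ~ N(by, sy²)`). The
  weighted median is consistent while <50% of weight is on invalid
  instruments.
* **MVMR**: weighted least squares of `by` on the J×K matrix of exposure
  effects, no intercept, weights 1/sy², dispersion floor
  `max(1, RSS/(J−K))`, normal p-values. Requires J > K and a full-rank
  design; with K = 1 it reproduces univariable IVW exactly. Instruments are
  the union of each exposure's instrument set, harmonized jointly; SNPs
  missing from any table are dropped and logged. Weak-instrument status is
  a flag (any exposure with marginal min F ≤ 10), never a hard block.
* **MR-PRESSO**: observed residual sum of squares about leave-one-out IVW
  fits, `RSS = Σ (by_j − beta_{−j}·bx_j)²/sy_j²`, compared against a
  parametric null (`by* ~ N(beta_{−j}·bx_j, sy_j²)`, leave-one-out
  estimates recomputed per draw). The global p-value uses add-one
  smoothing, `p = (1 + #{RSS* ≥ RSS})/(nsim+1)`, so it lives in
  `[1/(nsim+1), 1]`. Per-SNP outlier p-values compare each observed squared
  residual with its simulated distribution and are Bonferroni-adjusted by J.
  The distortion statistic is `(beta_all − beta_corrected)/beta_corrected`;
  its null replaces the outlier rows with bootstrap resamples of inlier
  rows. (A literal "relabel random SNPs as outliers" null would give
  p ≈ #outliers/J for a genuine dominant outlier and cannot detect
  distortion; the resampling scheme is the established one.) All PRESSO
  randomness flows through one generator seeded from the caller, so equal
  seeds give bit-identical results.

## Error propagation (mediation calculus)

First-order Gaussian rules with independence assumed between the
propagated terms:

* `se(a·b) = sqrt(a²·se_b² + b²·se_a²)`
* `se(a/b) = |a/b|·sqrt((se_a/a)² + (se_b/b)²)`, limit `se_a/|b|` at a = 0
* `se(a±b) = sqrt(se_a² + se_b²)`

Independence of step 1 and step 2 is justified by the two-sample design
(estimates from different datasets); independence of the indirect and total
effects is **not** exact, because they share instruments — the quotient SE
for the proportion mediated neglects that covariance and is a documented
limitation. Proportions may legitimately fall outside [0, 1] under
inconsistent mediation; the package flags (|proportion| > 1) rather than
errors. Product-method proportions of overlapping mediators need not sum to
the combined difference-method proportion, and the pipeline asserts no such
additivity.

## Harmonization, instruments, gates

* Harmonization aligns every table to the first exposure's effect allele:
  identical alleles kept, swapped alleles negate beta and complement EAF,
  strand flips resolved through A↔T / C↔G. Palindromic (A/T, C/G) SNPs
  carry no strand signal in their labels; the default policy orients them
  by allele frequency and drops them when either EAF is missing or inside
  (0.42, 0.58). Unresolvable pairs are dropped with a reason; the drop log
  is part of the output.
* Duplicate SNP ids within a file keep the smallest p-value row
  (deterministic).
* Instrument selection: genome-wide significance `p < 5e-8` (strict
  inequality), greedy LD clumping against a supplied r² matrix (index SNP =
  smallest p, ties broken lexicographically; removal at `r² ≥ threshold`,
  default 0.001, so the kept set is pairwise below the threshold), and
  per-SNP `F = (beta/se)²` with the conventional F > 10 screen.
* Two-step gates: a mediator enters mediation only if its step-1 IVW
  p-value is below the suggestive threshold (default 0.05) and its step-2
  MVMR p-value is below the same threshold; excluded mediators are reported
  with flags `excluded_step1` / `excluded_step2`. Bonferroni thresholds
  (0.05 / family size) are annotated per mediator family but never gate.
  Families are explicit configuration, not inferred.

## Synthetic-data generator

`synthetic.simulate_study` draws per-SNP true effects
`gamma_j ~ |N(0, gamma_sd²)|` for the exposure and `kappa ~ |N(0, kappa_sd²)|`
for each mediator's own instruments (effect alleles coded in the
trait-increasing direction, as GWAS lead SNPs conventionally are — this
keeps directional pleiotropy expressed in a fixed orientation so the Egger
intercept can recover it). True outcome effects follow the structural
model; horizontal pleiotropy adds `theta_j ~ N(pleiotropy_mean,
pleiotropy_sd²)` to a chosen fraction of exposure instruments. Observed
effects add `N(0, se²)` noise and report the `se` scale as the standard
error; p-values come from the normal z-score, floored at 1e-300 to remain
in (0, 1].

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `j_exposure` | 143 | instrument count of a modern consortium-scale binary-trait GWAS |
| `j_mediator` | 50 | typical clumped instrument count for a continuous trait |
| `gamma_sd`, `kappa_sd` | 0.08 | with the se scales below, typical instrument F ≈ 25–100 |
| `se_x` | 0.01 | log-odds SE for a ~0.5 M-participant case-control GWAS |
| `se_m` | 0.005 | SD-unit SE for a UKB/ICBP-scale (~10⁵–10⁶) continuous-trait GWAS; smaller values matter because instrument selection happens in the same sample, and an unrealistically noisy mediator GWAS would inject winner's-curse attenuation that the real data sources do not have |
| `se_y` | 0.02 | log-odds SE for a ~60 k-case outcome GWAS |
| `alpha, beta_m, beta_d` | 0.5, 0.4, 0.1 | moderate mediation: total 0.3, proportion 2/3 |

What the generator deliberately does **not** emulate: LD between
instruments (identity matrix; clumping is exercised against constructed
matrices in tests), allele-frequency-dependent SE, liability-scale
subtleties of binary outcomes, sample overlap between the two samples, and
mediator-mediator causal paths. Passing recovery tests therefore show
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Measured operating characteristics

The test suite recomputes these; the numbers below are what it observed at
the seeds it fixes.

* 95%-CI coverage over 200 replicates at generator defaults: total effect
  0.950, exposure direct effect 0.985, mediator direct effect 0.915 — all
  inside the accepted [0.91, 0.985] band. Mean bias of the estimated
  proportion mediated: −0.004 (|bias| < 0.02). The mediator-side coverage
  sits lowest because instrument selection in the mediator sample leaves a
  residual winner's curse.
* Empirical size of the Egger-intercept and PRESSO global tests at
  nominal 0.05, measured over 500 no-pleiotropy replicates with very strong
  instruments (`se_x = 0.002`, where the first-order null model of both
  tests holds): 0.038 and 0.050. At the default `se_x = 0.01` both are
  mildly anticonservative (≈0.06–0.07) because the null models condition on
  `bx` while the data carry exposure-side noise — an inherent property of
  the first-order approximation worth remembering when instrument strength
  is marginal.
* An injected dominant outlier is flagged by the PRESSO outlier test at
  all 20 seeds tried (nsim = 200).

## Numerical and design choices

* Dispersion factors are floored at 1 (`max(1, ·)`) so random-effects /
  overdispersed SEs never undercut the fixed-effect SE; on exact fits
  (RSS = 0) SEs are computed from the unscaled covariance and stay finite.
* IVW with a single SNP falls back to the Wald ratio (tagged `wald`).
* `bx = 0` SNPs are allowed in IVW (they contribute zero weight via the
  closed form) but are excluded with a reason from per-SNP ratio tables,
  and raise for the Wald ratio itself.
* Heterogeneity Q is computed as `Σ (by − beta·bx)²/sy²`, the
  division-free algebraic equivalent of the ratio-space form, so zero-`bx`
  SNPs are safe.
* Report tables round only at serialization (effects/SE/OR to 2 decimals,
  proportions to whole percent, half-up), with full-precision companions;
  reruns with equal config and seeds are byte-identical, verified by hash.
* Problem sizes in the slower test tiers (200 recovery replicates, 500
  calibration replicates at nsim = 200, bootstraps of 100–300 in pipeline
  tests) were chosen to make the Monte-Carlo error bands quoted above
  meaningful while keeping the default suite in the tens of seconds.

## Known limitations

* No covariance terms anywhere in the error propagation (see above).
* No Steiger directionality filtering, mode-based estimators, MR-RAPS,
  conditional F-statistics, or MVMR-Egger.
* LD clumping is r²-threshold-only against a supplied matrix; no
  window/position logic and no LD estimation from genotypes.
* The worked-example reproduction inherits the rounding of the published
  inputs; agreement is expected to about one percentage point, and pairs
  with small total effects (e.g. stroke) amplify that rounding.
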