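# Methods

This note records the statistical model implemented by `enrichsurv`, the
choices made where the design was genuinely open, and what the test suite
does and does not establish.

## The enrichment chain

For each enrichment threshold *t* (the biomarker percentile below which
patients are screened out), the pipeline is:

1. **Eligibility cutoff.** The cutoff is the nearest-rank empirical
   *t*-quantile of the oriented biomarker (inverse empirical CDF); a patient
   is eligible if their value is ≥ the cutoff, so ties at the cutoff are
   included. Nearest-rank avoids interpolation ambiguity and makes runs
   exactly reproducible. The package orients data on ingestion so that
   higher biomarker always means higher risk; analyses are therefore
   invariant to the raw direction of the marker.
2. **Subgroup survival.** Kaplan-Meier product-limit estimate on the eligible
   subset, with Greenwood pointwise variances (ties resolved the standard
   way: events precede censorings at the same time; the Greenwood sum is
   taken as 0 where Ŝ = 0). Curves are right-continuous step functions with
   Ŝ(0) = 1. Strict evaluation refuses to extrapolate beyond the last
   observed time; lenient mode carries the last value forward with a logged
   warning (used inside the bootstrap, where a resample may end slightly
   early).
3. **Event rates.** Fixed-duration designs evaluate Ŝ at the trial length T.
   Accrual designs assume uniform entry over the accrual period *a* followed
   by follow-up *f*, and average the event probability over follow-up lengths
   with Simpson's rule: p̂C = 1 − [Ŝ(f) + 4Ŝ(f+a/2) + Ŝ(f+a)]/6, and
   p̂T likewise with each survival value raised to the treatment HR. With
   exponential survival the Simpson average agrees with the exact
   uniform-entry integral to ~10⁻⁴, which the tests verify.
4. **Sample size, screening, cost.** N = 2N₀/(p̂C + p̂T) with N₀ from the
   log-rank events formula (kept unrounded internally; N₀ is treated as
   fixed, so all uncertainty flows through p̂). Screened = N/(1−t); the
   identity screened·(1−t) = N holds exactly before display rounding. Cost is
   C₁N + C₂N/(1−t) in constant mode. Display rounding (event rates to whole
   percent, patient counts to whole patients, half away from zero) happens
   only in the output table; full-precision parallel columns are always
   written.
5. **Uncertainty.** Fixed designs: delta method,
   SD(p̂) = (1 + HR·Ŝ^(HR−1))·SD(Ŝ) and SD(N) = (2N₀/p̂²)·SD(p̂); the
   reported event-rate SE is SD(Ŝ) itself since p̂C = 1 − Ŝ. Accrual
   designs: nonparametric bootstrap (default B = 200, seeded) that resamples
   subjects with replacement and re-derives the cutoff, subgroup and curve
   each time; resamples with an empty subgroup are skipped and logged, and
   more than 10% skips is an error. The reported cost-reduction column
   compares unrounded costs against the t = 0 row of the same run.

## Time-dependent per-patient cost

When the per-patient trial cost is a rate per unit time on study before the
endpoint, the expected time on study is the restricted mean of the step
curve: for fixed designs, the restricted mean to T computed per arm (control
from Ŝ, treatment from Ŝ^HR) and averaged with equal arm weights; for
accrual designs, the same quantity at follow-up lengths f, f+a/2, f+a
combined with Simpson weights (1,4,1)/6, mirroring the event-rate treatment.
This construction is the package's own choice of a formula consistent with
the rest of the chain; published total-cost columns for comparable examples
could not be reconciled with any constant-cost formula (see Limitations), so
cost outputs are validated by arithmetic properties and by the qualitative
cost-shape scenario rather than by printed cost tables.

## Nearest-neighbour estimator

For fixed-duration designs an alternative subgroup estimator is available
that tolerates censoring dependent on the biomarker: conditional survival
Ŝ(t | X = xᵢ) is computed by a weighted product-limit over the subjects whose
biomarker percentile lies within ± `span` of subject *i* (box kernel;
default half-width 0.25·n^(−0.2), the convention popularized with this
estimator), and the subgroup curve is the average of the conditional curves
over eligible subjects — an estimate of P(T > t, X ≥ c)/P(X ≥ c), monotone
in *t* and, up to smoothing error, in the threshold. Published variants of
this estimator differ in kernel and weighting details; the box-kernel
variant was chosen for reproducibility and is documented here because the
choice affects third-decimal agreement with subgroup-KM (observed
|ΔŜ(T)| ≈ 0.004 at n = 5000, tolerance 0.02 in tests). Its standard errors
are approximated by the Greenwood errors of the subgroup-KM fit — adequate
for the ±1 SE display bands, not for formal inference. Accrual designs use
KM only; requesting NNE with an accrual design is a configuration error.

## Simulator

Cohorts are generated under Weibull proportional hazards: a subject with
standardized biomarker x has hazard (k/a_W)(t/a_W)^(k−1)·e^(βx), i.e. a
Weibull with shared shape k and subject scale a_W·e^(−βx/k), where
β = log(per-SD hazard ratio). Latent times are drawn by inverse transform
from the closed-form quantile function (exactly reproducible from the seed;
biomarker draws precede the survival uniforms in the stream), and are
administratively censored at the anchor time T. Biomarker values are drawn
standard normal or standard lognormal and standardized to sample mean 0 and
sample SD 1 (lognormal after exponentiation, preserving right skew), which
makes β a per-SD log-hazard exactly for both shapes.

**Anchoring.** The scale a_W is calibrated from "survival probability p at
time T". Two conventions are supported because they differ materially for
strong markers:

* `anchor="population"` (default): a_W solves
  meanᵢ exp(−(T/a_W)^k e^(βxᵢ)) = p, so the cohort's *marginal* survival at
  T is p. This matches the natural reading "the cohort's event rate by T is
  1−p", and it is the convention under which the package reproduces
  published enrichment analyses of a strongly prognostic simulated marker.
* `anchor="subject"`: a_W = T/(−ln p)^(1/k), anchoring the mean-biomarker
  subject (x = 0). For a weak marker the two are nearly identical; for
  HR 2.8/SD the subject convention yields a cohort event rate ~4–5
  percentage points higher than 1−p, because the frailty e^(βX) has mean
  e^(β²/2) ≈ 1.7.

Optional independent exponential censoring is available behind
`censor_rate` but defaults off; by default censoring is administrative only,
so event = 0 exactly when the observed time equals T.

**What the simulator does not emulate:** covariate-dependent censoring,
measurement error in the biomarker, non-proportional or time-varying marker
effects, dropout, or delayed entry. Tests that pass on simulated cohorts
therefore establish correctness of the estimation chain under proportional
hazards with administrative censoring — not robustness to those real-data
features.

## Numerical choices and problem sizes

* Normal quantiles from scipy; the events formula is checked in tests
  against stdlib `statistics.NormalDist` to 6 significant figures.
* The population-anchor scale is solved by Brent's method on
  [10⁻⁴T, 10⁵T] with xtol 10⁻¹⁰T.
* Delta-method SDs are verified against central-difference differentiation
  to 4 significant figures across Ŝ ∈ {0.5, 0.8, 0.95}, HR ∈ {0.5, 0.8}.
* At Ŝ = 0 with HR < 1 the delta slope diverges; rates are still returned
  and the SD is flagged NaN.
* Reference-scale checks use n = 5000 cohorts with medians over 10 seeds,
  and n = 100 000 for simulator calibration invariants (anchor within 3
  Monte-Carlo SEs; constant-hazard check within 10% between half-periods).
  Bootstrap SEs use B = 200.
* Default analysis floor n ≥ 20 (configurable); subgroups must keep ≥ 10
  subjects above the cutoff. These are stability guards, not estimates of a
  minimum informative sample size.

## Known limitations

* Cost columns of published example tables for this methodology cannot be
  reproduced from the stated constant-cost formula (their printed cost
  increases exceed what any positive cost pair allows); `enrichsurv`
  implements the formula as stated. Relatedly, the claim that a weak marker
  (HR 1.2/SD) makes enrichment strictly cost-increasing at a 1:10
  screening-to-trial cost ratio does not hold under the stated formula —
  seed-averaged cost declines ~3% out to t ≈ 0.30 before rising. The test
  asserting that claim fails and is left failing rather than weakened. The
  strong-marker U-shape (interior cost minimum at the 70–80% level) does
  reproduce.
* Median sample sizes at t ∈ {0, 0.05} in the reference accrual analysis sit
  ~5.3% above the published single-realization values, just outside a ±5%
  band (event rates agree within 1–1.8 pp everywhere; all other sample-size
  cells within 5%). The discrepancy is consistent with the published table
  being one simulation draw ~1.3 Monte-Carlo SE above its own anchor.
* Equal randomization only; no non-inferiority designs, interim analyses,
  dropout modelling, competing risks, left truncation, or covariate-adjusted
  survival models.
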