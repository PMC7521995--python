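# Methods

This note records the statistical model, the numerical choices, and what
the synthetic-data generator does and does not establish.

## PRS construction

A PRS is a weighted sum of effect-allele dosages, `raw_i = Σ_v w_v g_iv`.
Dosage files may count the opposite allele; harmonization flips
`g → 2 − g` when the counted/other alleles are swapped relative to the
weight table. Strand-ambiguous SNPs (A/T, C/G) are matched by allele label
only, with a logged warning — resolving strand requires frequency
information we deliberately do not consult. Missing dosages are imputed to
`2f` (their Hardy–Weinberg expectation at effect-allele frequency `f`) by
default; a `drop` policy (zero contribution) and a strict `error` policy
are available.

Standardization is `(raw − mean)/SD` with an externally supplied reference
SD (population controls for breast scores, unaffected carriers for ovarian
scores). Only the SD affects hazard ratios; centering moves the baseline
only, and we center so that the median score sits near zero. Percentile
thresholds are type-7 (linear interpolation) quantiles of the reference
subset; categories are half-open `[lower, upper)` so boundary values fall
to the higher bin.

## Censoring and analysis datasets

Breast outcomes censor at the first of breast diagnosis, ovarian
diagnosis, risk-reducing mastectomy, last follow-up, or age 80; a
diagnosis exactly tied with a censoring age counts as an event (diagnosis
leads the censoring list). ER-specific outcomes additionally censor
opposite-ER diagnoses and exclude affected carriers with missing ER
status. The ovarian outcome censors at RRSO instead of mastectomy; whether
a breast diagnosis also censors ovarian follow-up is configurable
(`censor_ovarian_at_bc`, default true). Retrospective datasets enter the
risk set at age 0 on the age time scale; prospective datasets enter at
recruitment and exclude carriers affected (or out of follow-up) before
recruitment. Strata are country × Ashkenazi ancestry; the cluster variable
is the family identifier. Family history enters as two indicators (one
affected relative; two or more) against none.

## Sampling-weight calibration

Clinic-based recruitment over-represents affected carriers, biasing naive
survival estimates. Within age bin `j`, affected exits are weighted
`p_j/q_j` and unaffected exits `(1−p_j)/(1−q_j)`, where `q_j` is the
observed affected fraction among exits and `p_j = E_j/N_j` the expected
fraction, with `E_j` the events implied by the external incidence
integrated over the cohort's weighted person-time in the bin. Because the
weights change person-time, the pair (weights, `p_j`) is iterated to a
fixed point (sup-norm tolerance 1e-12, ≤200 iterations; convergence is
geometric in practice). At the fixed point the weighted affected fraction
equals `p_j` identically and the weighted age-specific incidence equals
the external curve bin by bin.

Default bins are the external curve's own pieces, so "agreement" is
against a constant rate per bin; bins lacking affected or unaffected exits
are automatically merged leftward. Explicitly supplied bins are used as
given and degenerate bins raise an error instead.

Known behavior: the estimator carries a small residual bias under extreme
oversampling. In the hardest configuration we test (a 17%-cumulative-risk
outcome oversampled to ~37% affected), the recovered per-SD hazard ratio
averages ≈1.40 against a generating 1.44 (−3% on the ratio scale); the
other configurations recover within Monte-Carlo noise. This mirrors the
mild attenuation reported for weighted-cohort estimators and is inherent
to calibrating by exit-bin status rather than the (unknown) true inclusion
probabilities.

## Cox fitting

The weighted, stratified partial likelihood (Efron ties) is maximized by
lifelines' Newton solver (coefficient precision 1e-9, step-halving, ≤200
steps); a brute-force likelihood maximization on ≤6-subject data
cross-checks it in the test suite. The family-clustered sandwich
covariance is computed in-package from weighted score residuals
`w_i ∫ (x_i − x̄(t)) dM_i(t)` with Breslow-style risk sets, honouring
delayed entry and strata: `V = A⁻¹ (Σ_g U_g U_gᵀ) A⁻¹` with `A⁻¹` the
model-based covariance and `U_g` the family-summed residuals. On tie-free
data this reproduces lifelines' robust standard errors to four digits; at
heavy ties the two differ slightly (both are Breslow approximations
evaluated at the Efron maximum). Confidence intervals are
`exp(β ± 1.96·SE_robust)`.

The PRS×age model treats the PRS as time-varying with covariate value
`z·t` at risk-set age `t`, implemented by episode-splitting every subject
at the distinct event ages inside their at-risk window — exact for the
risk-set evaluation, and tractable because ages are recorded in whole
years. The main-effect hazard ratio applies at age 0 and decays by the
interaction ratio per year (no centering), matching an age-in-years
interaction.

Likelihood-ratio tests use `2Δℓ` of the (weighted) log partial likelihood
against a chi-square; with non-unit weights this reference is approximate
and a caveat is logged. The heterogeneity test compares per-group PRS
slopes against a common slope (nested by reparametrization, so the df is
passed explicitly); the categorical-vs-continuous comparison is made
properly nested by testing whether the eight bin indicators add to the
continuous model. Percentile-category fits also report the hazard ratio
expected under the continuous model at each bin,
`exp(β·(E[z|bin] − E[z|reference]))` with truncated-normal bin means.

Harrell's C forms pairs within strata (an event versus any later exit,
ties in the linear predictor counting one half) and pools the concordant
and comparable counts across strata; the standard error is a seeded
bootstrap over families, resampling clusters with the fitted linear
predictor held fixed.

## Constrained absolute risks

Given per-SD log HR `β(t)` and an external average incidence `λ̄(t)`, the
baseline hazard must satisfy, at every age, the prevalence-weighted
mixture identity `λ̄ = λ₀ Σ p_k S_k RR_k / Σ p_k S_k` — depletion of
susceptibles makes `λ₀` fall increasingly below `λ̄/E[RR]`'s naive value
with age. Rather than the explicit forward update (which conserves the
hazard identity but drifts on cumulative risk at an annual step), each
year solves the scalar equation
`Σ p_k S_k(t)·exp(−RR_k(t)·δ) = S̄(t)·exp(−λ̄(t))` for the baseline
increment δ by Brent's method (tolerance 1e-15), so the mixture-average
survival tracks the external curve exactly; the instantaneous hazard
identity then also holds exactly at grid ages. For constant β both
formulations coincide in the continuum limit; the rare-disease limit
`λ₀ → λ̄·exp(−β²/2)` is verified to 1% in tests.

The solver grid is annual from the curve's first age (18 for the bundled
fixtures) to 80, with piecewise-constant hazards (exact for
piecewise-constant `λ̄`). The default mixture is 201 equal-probability
bins of the standard normal with truncated-normal bin means; reported
percentiles are evaluated at exact `z = Φ⁻¹(pct)`, removing
discretization bias from headline risks (doubling the resolution moves
them by <0.5 percentage points). The model is single-decrement (no
competing mortality), and no confidence intervals are attached to
predicted risks — they inherit the (unquantified) uncertainty of the
external incidence curves. Subgroup risks (family history, variant
location) re-solve independently per subgroup curve with the shared
hazard ratio.

## Synthetic cohorts

The generator encodes the stated world of the analysis: standard-normal
standardized PRS; within-family correlation 0.5 via a shared family
component (`z = √ρ·family + √(1−ρ)·individual`) in sib-pairs/trios;
disease ages by inverse-CDF of the cumulative hazard
`Σ δ_u exp(β(u)z)` where the baseline increments δ come from the
constrained solver — so the population incidence equals the stated
external curve by construction; independent censoring by risk-reducing
surgery (constant hazard from age 25; default 0.008/yr mastectomy,
0.012/yr RRSO — plausible clinic uptake), a competing cancer (0.002/yr),
and end of follow-up (normal, mean 55 SD 12, truncated to [19, 80]).
Recorded ages are rounded to whole years, reproducing the heavy ties of
real cohorts. Ascertainment is two-phase sampling of families by proband
status until the target affected fraction (default 50%) is reached, the
pool growing adaptively for rare outcomes. ER status is positive with
probability 0.35 (most BRCA1 tumors are ER-negative) and missing with
probability 0.30 (missingness is substantial in real pathology data).
All randomness flows from a single seed; rerunning a config reproduces
the cohort byte for byte.

What a green test establishes: the pipeline recovers generating
parameters from data satisfying its own assumptions, and its
deterministic constraints hold exactly. What it does not: robustness to
model misspecification (non-normal PRS, non-proportional hazards beyond
log-linear age effects, informative censoring, real ascertainment
mechanisms, genotyping or imputation error), which no synthetic fixture
of this kind can certify.

## Degenerate inputs and tie-breaks

Empty weight tables, non-ACGT alleles, duplicate variant ids, nonpositive
reference SDs, degenerate (constant) percentile references, event ages
after last follow-up, weight bins without both affected and unaffected
exits (when bins are explicit), eventless datasets, single-group
interaction requests, and out-of-range percentiles all raise typed
errors naming the offending items. Ties: diagnosis beats censoring at the
same age; exits exactly on a bin edge count in the lower bin; percentile
boundary values go to the higher category; tied linear predictors count
half in concordance.
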