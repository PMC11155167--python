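# Methods

## Model

For subject i with binary outcome Y_i, binary exposures X_ik observed at
K questionnaire waves, and realized lags t_ik (months between the wave-k
response and the outcome assessment; the outcome sits at lag 0), the
distributed lag logistic model constrains the per-lag effect to a
fractional polynomial,

    logit P(Y_i = 1) = β₀ + Σ_k f(t_ik) X_ik + ηᵀZ_i,
    f(t) = δ₀ + δ₁ t + δ₂ t² + δ₃ √t.

Substituting f collapses the exposure terms into W_i = Σ_k B(t_ik) X_ik
with B(t) = (1, t, t², √t), so the model is an ordinary logistic
regression on [1 | W_i | Z_i] and is fitted by Newton/IRLS maximum
likelihood (statsmodels `Logit`; relative log-likelihood tolerance
1e-10, at most 100 iterations). Non-convergence, perfect separation and
singular information are reported states, never silent estimates.

The lag effect at any t is f̂(t) = T(t)ᵀδ̂ with delta-method variance
T(t)ᵀ Cov(δ̂) T(t), where Cov(δ̂) is the corresponding block of the
inverse observed information. Odds-ratio curves use pointwise two-sided
Wald intervals exp(f̂ ± z₀.₉₇₅ SE) with z₀.₉₇₅ = 1.959964; a lag is part
of a critical window when its interval excludes 1, and windows are the
maximal consecutive runs of such grid lags.

Assumptions worth stating: effects of exposures at different waves are
additive on the log-odds scale; the lag-effect profile is smooth enough
for a 4-term fractional polynomial; exposures are binary indicators;
covariates act additively and are categorical (reference-cell dummy
encoding, reference = first declared category).

## Numerical choices

- The raw basis columns span wildly different magnitudes (t² up to ~4000
  against a unit constant), so `fit_dlm` rescales each W column by its
  max-abs before fitting and maps coefficients and covariance back
  exactly. This is a pure reparametrization; it changes nothing
  statistically.
- Identifiability guard: after scaling columns to unit norm, a design
  condition number above 1e10 aborts the fit with a message naming the
  near-collinear columns. The canonical failure is three shared lags
  with the 4-term basis (rank 3); per-subject response-time jitter is
  what makes the model estimable in cohort data, and this is documented
  in the error text.
- Tiny negative delta-method variances from round-off (|v| < 1e-12) are
  clipped to zero; anything more negative propagates as an error.
- The default evaluation grid is the integer lags spanning the observed
  lag range (15..42 for the three-wave cohort); intervals widen toward
  the ends where data thin out.
- The AR(1) Cholesky factorization falls back once to a 1e-12 diagonal
  jitter; at γ = 0.9999 the plain factorization succeeds in double
  precision.

## Comparator models

The Single model fits outcome ~ intercept + X_k (+ covariates) once per
wave; the Multi model enters all K exposures jointly. Estimates are
indexed by canonical wave time (6k in the simulation study, the modal
lag in cohort data) and ignore per-subject jitter by construction, as
their model equations do. In the simulation study neither includes
covariates, because the generating outcome model contains none. With K
shared lags and a K-term basis the DLM reproduces the Multi model
exactly (tested); the constant-only basis reduces it to a logistic
regression on the exposure count (tested to 1e-8).

## Simulation study

Subjects answer K = 10 questionnaires at nominal lags 6k; realized lags
add a discrete jitter with P(6k) = 0.45, P(6k±1) = 0.15, P(6k±2) = 0.10,
P(6k+3) = 0.05 — the support is deliberately asymmetric (+3 with no −3).
Exposures have marginal prevalence p_k = 0.2 and are correlated through
a Gaussian copula: V ~ N(0, C) with c_ij = γ^|i−j|, X_k = 1 iff
V_k < Φ⁻¹(p_k), for γ ∈ {0, 0.975, 0.9999}. Outcomes are Bernoulli with
logit μ_i = −2.2 + Σ_k X_ik β(t_ik); the true curve β(·) is evaluated at
the subject's realized jittered lag, not the nominal 6k — this is the
reading under which jitter straddling an effect-window boundary produces
the boundary biases the misspecified models show, and it is the
convention used throughout.

Scenarios: (1) β(t) = 0.15 everywhere; (2) a downward-opening quadratic,
default β(t) = −1.5e-4·(t − 33)² + 0.2, positive over the observed lags
4..63; (3) a pulse, default height 0.25 on [36, 47]. The scenario-1
numbers are fully determined; the scenario-2/3 magnitudes are this
package's own defaults (configurable constructor parameters) and are not
externally calibrated — conclusions drawn from them are qualitative.

Replication harness: each replication draws a fresh dataset
(n = 10000 default) from a counter-based substream of the master seed,
so any single replication is re-runnable in isolation and results do not
depend on which models are requested. Metrics per model and canonical
time 6k: bias = mean(β̂) − β(6k); EmpSE = sample SD (n−1 denominator —
the usual simulation-study convention; at 1000 replications the
alternative changes nothing visible); MSE = mean squared deviation from
β(6k). All are reported raw and ×100. The identity
MSE = bias² + EmpSE²·(r−1)/r holds to 1e-12 per cell and is tested.
Failed replications are excluded and counted, never re-seeded, and a
warning is surfaced when more than 1% fail. The default test suite runs
1000 replications at γ = 0 and 0.975 and 500 at γ = 0.9999 (a few
minutes on one CPU); the acceptance script uses a 200-replication
reduced mode.

## Synthetic three-wave cohort

The generator emulates the structure of a large birth-cohort
questionnaire study: three waves at modal lags 18, 30 and 39 months
before an age-3 outcome, symmetric ±3-month response-delay jitter
(probabilities 0.05/0.10/0.15/0.40/0.15/0.10/0.05), per-wave exposure
prevalences (0.125, 0.172, 0.143), latent wave-to-wave copula
correlation 0.975 (high ownership persistence), five categorical
covariates (child sex, maternal asthma, preterm birth, income, area)
with log-odds effects in the 0.3–0.8 range for the known risk factors,
and an injected true effect curve β(t) — by default log(1.07) on lags
30–36, mirroring an application-scale finding; set it to 0 for a null
cohort. The intercept is calibrated at generation time by root-finding
so the expected outcome prevalence hits the 0.17 target under whatever
configuration is chosen; the calibrated value is recorded in the truth
sidecar along with everything else needed for recovery tests.

What this generator does *not* emulate: missing data and loss to
follow-up, the full covariate set of a real cohort, regional
heterogeneity beyond one area factor, exposure measurement error, and
any dependence of response delay on exposure or outcome. Passing
recovery tests on it therefore demonstrates correctness of the
estimation machinery under the stated generating process, not
robustness to those real-data complications.

## Window detection: power and multiplicity

Two properties of the pointwise-Wald window rule matter for
interpreting experiments on the synthetic cohort:

- **Power.** An effect confined to lags 31–34 is carried only by the
  ~30% of wave-2 responses whose jittered lag lands at 31–33, so an
  application-scale OR of 1.07 is essentially undetectable at n = 60000
  (a few percent detection). The window-detection experiment in the test
  suite therefore injects OR 2.0, sized by an a priori power analysis
  (OR 1.5 gave ~88% detection in pilots, OR 2.0 ~100%) so that the test
  exercises the detection machinery rather than borderline power.
- **Multiplicity.** Windows are read from pointwise 5% tests on a smooth
  4-parameter curve evaluated at ~28 grid lags. The *pointwise* type-I
  rate is controlled at 5% (tested), but the family-wise chance of at
  least one significant lag on a null cohort is roughly
  1 − 0.95⁴ ≈ 18%, matching the ~80% observed no-window rate. Users
  should treat a single stray significant lag with corresponding
  caution; no simultaneous-band correction is applied, matching the
  usual practice for these curves.

Whether reported intervals should instead be simultaneous was an open
design choice; pointwise Wald was chosen as the standard output of
logistic MLE software and the convention such odds-ratio-curve figures
use.

## Known limitations

- The fractional-polynomial family is fixed (configurable powers, but no
  data-driven basis selection); step-like true effects are smeared
  (scenario 3 shows ~50%-of-truth bias inside the pulse).
- No missing-data handling; complete cases are assumed.
- Continuous exposures and penalized/spline/Bayesian lag models are out
  of scope.
- The lag→age translation in window reports assumes a fixed outcome age
  (36 months); per-subject outcome ages are not modelled.
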