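# fpdlm — fractional-polynomial distributed lag models for binary exposures

`fpdlm` estimates *critical windows* — the lag ranges over which a
time-varying binary exposure is associated with a later binary outcome —
for study designs like repeated questionnaire waves in a birth cohort
(e.g. pet ownership asked at mid-pregnancy, 6 months and 1.5 years,
wheezing assessed at age 3). Repeated exposures of this kind are highly
persistent, so entering them jointly in one logistic regression inflates
every standard error (multicollinearity), while analysing each wave
separately lets every coefficient absorb the effects of all the other
waves. The distributed lag model (DLM) implemented here resolves this by
constraining the lag-specific log-odds effect β(t) to a fractional
polynomial of the lag t (months before the outcome assessment):

    f(t) = δ₀ + δ₁·t + δ₂·t² + δ₃·√t

With per-subject exposures X_k observed at realized lags t_k, the
constrained model collapses to an ordinary logistic regression

    logit P(Y = 1) = β₀ + δᵀW + ηᵀZ,     W = Σ_k (1, t_k, t_k², √t_k)·X_k

so any standard MLE fits it. The effect at any lag is reconstructed as
f̂(t) = T(t)ᵀδ̂ with delta-method variance V(f̂(t)) = T(t)ᵀ Cov(δ̂) T(t),
where T(t) = (1, t, t², √t), giving an odds-ratio curve with pointwise
95% Wald intervals; maximal runs of lags whose interval excludes 1 are
reported as critical windows.

The package also provides:

- the two standard baselines (**Single**: one logistic fit per wave;
  **Multi**: all waves in one fit),
- a **simulator** for correlated binary exposure trajectories
  (Gaussian-copula thresholding of a latent AR(1) normal vector,
  c_ij = γ^|i−j|) with jittered questionnaire times and three
  true-effect scenarios,
- a **replication-study harness** reporting bias, empirical SE and MSE
  per model and canonical time,
- a **synthetic three-wave cohort generator** with covariates, a
  calibrated outcome prevalence and an explicitly injected true effect
  curve, for parameter-recovery and window-detection experiments.

Identifiability note: with exactly three shared lags the four-term basis
is rank-deficient; per-subject jitter in response times is what makes
the four coefficients estimable. Fitting refuses (with a diagnostic)
when the design condition number exceeds 1e10.

## Worked example

```python
import math
from fpdlm import CohortConfig, fit_dlm, effect_curve, detect_critical_windows, generate_cohort

config = CohortConfig(effect_log_or=math.log(1.3))       # truth: OR 1.3 on lags 30-36
cohort, truth = generate_cohort(60000, seed=42, config=config)
fit = fit_dlm(cohort)
effects = effect_curve(fit)                              # integer lags 15..42
print(detect_critical_windows(effects))
```

Running `python examples/fit_cohort_dlm.py` (the same analysis with
printing) gives:

```
 lag    OR   95% CI          significant
    15  0.900  (0.744, 1.089)  False
    ...
    30  1.177  (1.090, 1.271)  True
    33  1.183  (1.095, 1.278)  True
    36  1.145  (1.063, 1.233)  True
    ...
critical window: lags 26-38 months (child age -2 to 10 months ...)
```

The odds-ratio curve rises only where the injected effect acts, the
pointwise intervals exclude 1 there, and the detected window (lags
26–38) brackets the true window 30–36 — smoothing by the 4-parameter
curve widens the flagged range slightly. `examples/simulation_study.py`
prints the Single/Multi/DLM bias–EmpSE–MSE comparison at γ = 0.975, and
`examples/correlated_exposures.py` demonstrates the copula sampler
against the bivariate-normal orthant probability.

## Command line

```bash
fpdlm gen-cohort --n 60000 --seed 1 --out cohort.csv       # + cohort.truth.json
fpdlm fit --cohort cohort.csv --model dlm --out effects.csv
fpdlm simulate-study --scenario 1 --gamma 0.975 --reps 1000 --seed 7 --out-dir study/
```

Each command also accepts `--config file.yaml`; explicit flags override
file values. Results go to files, logs to stderr, and every command is
deterministic given its config.

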