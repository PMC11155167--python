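"""Fit the distributed lag model to a synthetic three-wave cohort.

Generates a cohort of 60,000 subjects with pet-ownership exposure asked
at three questionnaire waves (modal lags 18, 30 and 39 months before the
age-3 wheezing outcome), with a known effect injected on lags 30-36,
then fits the fractional-polynomial DLM and reads off the critical
window from the odds-ratio curve.  (The generator's default injected
effect, OR 1.07, is borderline at this sample size; the example injects
a clearly detectable OR of 1.3 so the window is visible.)
"""

import math

import numpy as np

from fpdlm import CohortConfig, detect_critical_windows, effect_curve, fit_dlm, generate_cohort

config = CohortConfig(effect_log_or=math.log(1.3))
cohort, truth = generate_cohort(60000, seed=42, config=config)
print(f"cohort: n={cohort.n}, waves at modal lags {truth['nominal_lags']}, "
      f"outcome prevalence {cohort.y.mean():.3f}")
print(f"injected truth: log-OR {truth['effect_log_or']:.4f} on lags {truth['effect_window']}")

fit = fit_dlm(cohort)
print(f"DLM converged in {fit.n_iter} Newton iterations; "
      f"delta = {np.array2string(fit.delta, precision=4)}")

effects = effect_curve(fit)  # integer lags spanning the observed range
print("\n lag    OR   95% CI          significant")
for e in effects[::3]:
    print(f"  {e.t:4.0f}  {e.or_:.3f}  ({e.ci_low:.3f}, {e.ci_high:.3f})  {e.significant}")

windows = detect_critical_windows(effects)
for lo, hi in windows:
    print(f"\ncritical window: lags {lo:g}-{hi:g} months "
          f"(child age {36 - hi:g} to {36 - lo:g} months for an outcome at 36 months; "
          "negative = before birth)")
if not windows:
    print("\nno critical window detected")

# The printed window should overlap the injected lags 30-36: the odds-ratio
# curve rises only where exposure carried the injected effect, and the
# pointwise 95% intervals exclude 1 exactly there.
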