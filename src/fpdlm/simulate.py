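"""Synthetic data generation for the simulation study.

Subjects answer K = 10 questionnaires at nominal lags 6k months
(k = 1..10); each subject's realized response time is jittered around 6k
by the discrete law P(6k) = 0.45, P(6k±1) = 0.15, P(6k±2) = 0.10,
P(6k+3) = 0.05 (the support is deliberately asymmetric: +3 but no −3).
Binary exposures with marginal prevalence p_k = 0.2 are correlated
across waves through a Gaussian copula: a latent draw
V ~ N(0, C) with AR(1) correlation c_ij = gamma^|i-j| is thresholded at
the standard-normal quantile g(p_k), so X_k = 1 iff V_k < g(p_k).
Outcomes are Bernoulli with logit
mu_i = -2.2 + sum_k X_ik * beta(t_ik), the true effect curve beta(t)
being evaluated at the subject's realized jittered lag t_ik.

Three true-effect scenarios: (1) constant beta(t) = 0.15; (2) a
downward-opening quadratic in t, always positive over the observed
lags; (3) a pulse confined to lags 36..47 (the model is then
misspecified, since no fractional polynomial is a step function).
Magnitudes for scenarios 2 and 3 are configurable; their defaults are
this package's own choice (see docs/methods.md) and carry no external
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .cohort import Cohort

__all__ = [
    "TIME_JITTER_OFFSETS",
    "TIME_JITTER_PROBS",
    "ar1_correlation",
    "sample_times",
    "sample_correlated_binary",
    "Scenario",
    "make_scenario",
    "simulate_outcomes",
    "SimulatedDataset",
    "generate_dataset",
]

TIME_JITTER_OFFSETS = np.array([-2, -1, 0, 1, 2, 3])
TIME_JITTER_PROBS = np.array([0.10, 0.15, 0.45, 0.15, 0.10, 0.05])


def ar1_correlation(gamma: float, K: int) -> np.ndarray:
    """AR(1) correlation matrix with entries gamma^|i-j|.

    ``gamma`` must lie in [0, 1); values as extreme as 0.9999 are
    accepted (the matrix stays positive-definite for gamma < 1).
    """
    if not (0.0 <= gamma < 1.0):
        raise ValueError(f"AR(1) parameter must be in [0, 1), got {gamma}")
    if K < 1:
        raise ValueError("K must be at least 1")
    idx = np.arange(K)
    return gamma ** np.abs(np.subtract.outer(idx, idx))


def sample_times(K: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the n x K matrix of realized questionnaire lags.

    Column k is i.i.d. from 6(k+1) plus the jitter law above.
    """
    offsets = rng.choice(TIME_JITTER_OFFSETS, p=TIME_JITTER_PROBS, size=(n, K))
    return 6 * np.arange(1, K + 1)[None, :] + offsets


def sample_correlated_binary(
    C: np.ndarray, p, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Correlated binary draws by Gaussian-copula thresholding.

    V ~ N(0, C); X_k = 1 iff V_k < Phi^{-1}(p_k), so each margin is
    exactly Bernoulli(p_k) while the latent AR(1) drives the dependence.
    A diagonal jitter of 1e-12 is applied once if the Cholesky
    factorization fails (relevant only for gamma extremely close to 1).
    """
    C = np.asarray(C, dtype=float)
    K = C.shape[0]
    p = np.broadcast_to(np.asarray(p, dtype=float), (K,))
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("exposure probabilities must lie strictly in (0, 1)")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        try:
            L = np.linalg.cholesky(C + 1e-12 * np.eye(K))
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"correlation matrix (K={K}) is not positive-definite even after "
                f"1e-12 diagonal jitter: {err}"
            ) from err
    V = rng.standard_normal((n, K)) @ L.T
    return (V < stats.norm.ppf(p)[None, :]).astype(int)


@dataclass(frozen=True)
class Scenario:
    """A true-effect scenario: beta(t) curve, exposure prevalence, intercept."""

    id: int
    effect_fn: Callable[[np.ndarray], np.ndarray]
    exposure_prob: float = 0.2
    intercept: float = -2.2
    notes: str = ""

    def true_effect(self, t):
        """Evaluate the true log-odds effect curve beta(t) at lag(s) t > 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("lags must be strictly positive")
        return self.effect_fn(t)


def make_scenario(
    id: int,
    *,
    exposure_prob: float = 0.2,
    intercept: float = -2.2,
    s2_peak: float = 0.2,
    s2_vertex: float = 33.0,
    s2_curvature: float = -1.5e-4,
    s3_height: float = 0.25,
    s3_window: tuple[float, float] = (36.0, 47.0),
) -> Scenario:
    """Build one of the three true-effect scenarios.

    Scenario 1: constant ``beta(t) = 0.15``.
    Scenario 2: downward-opening quadratic
    ``s2_curvature * (t - s2_vertex)**2 + s2_peak`` (positive over the
    observed lag range 4..63 at the defaults).
    Scenario 3: ``s3_height`` inside ``s3_window`` (inclusive), 0 outside.
    Scenario 2/3 magnitudes are package defaults, not externally
    calibrated; override them to probe other effect shapes.
    """
    if id == 1:
        fn = lambda t: np.full_like(np.asarray(t, dtype=float), 0.15)
        notes = "constant effect 0.15 at every lag"
    elif id == 2:
        if s2_curvature >= 0:
            raise ValueError("scenario 2 curvature must be negative (downward-opening)")
        fn = lambda t: s2_curvature * (np.asarray(t, dtype=float) - s2_vertex) ** 2 + s2_peak
        notes = f"quadratic, vertex {s2_vertex}, peak {s2_peak} (package default magnitudes)"
    elif id == 3:
        lo, hi = s3_window
        fn = lambda t: np.where(
            (np.asarray(t, dtype=float) >= lo) & (np.asarray(t, dtype=float) <= hi),
            s3_height,
            0.0,
        )
        notes = f"pulse of height {s3_height} on [{lo}, {hi}] (package default magnitude)"
    else:
        raise ValueError(f"unknown scenario id {id}; expected 1, 2 or 3")
    return Scenario(
        id=id, effect_fn=fn, exposure_prob=exposure_prob, intercept=intercept, notes=notes
    )


def simulate_outcomes(
    exposures: np.ndarray,
    times: np.ndarray,
    scenario: Scenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli outcomes from logit mu = intercept + sum_k X_k beta(t_k).

    The effect curve is evaluated at each subject's realized jittered
    lag, so jitter straddling an effect-window boundary produces the
    boundary biases the misspecified models exhibit.
    """
    exposures = np.asarray(exposures)
    times = np.asarray(times)
    if exposures.shape != times.shape:
        raise ValueError("exposures and times must share one (n, K) shape")
    beta = scenario.true_effect(times)
    mu = scenario.intercept + (exposures * beta).sum(axis=1)
    prob = 1.0 / (1.0 + np.exp(-mu))
    return (rng.random(mu.shape[0]) < prob).astype(int)


@dataclass
class SimulatedDataset:
    """One simulated dataset plus the truth that generated it."""

    exposures: np.ndarray
    times: np.ndarray
    outcomes: np.ndarray
    scenario: Scenario
    gamma: float
    seed: int | None = None

    def to_cohort(self) -> Cohort:
        return Cohort(y=self.outcomes, exposures=self.exposures, lags=self.times)


def generate_dataset(
    scenario: Scenario,
    gamma: float,
    n: int = 10000,
    K: int = 10,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Compose times, copula exposures and outcomes into one dataset.

    Fully reproducible: the same ``seed`` yields a bit-identical dataset.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    times = sample_times(K, n, rng)
    C = ar1_correlation(gamma, K)
    X = sample_correlated_binary(C, scenario.exposure_prob, n, rng)
    y = simulate_outcomes(X, times, scenario, rng)
    return SimulatedDataset(
        exposures=X, times=times, outcomes=y, scenario=scenario, gamma=gamma, seed=seed
    )
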