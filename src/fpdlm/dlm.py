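"""Fractional-polynomial distributed lag logistic model.

The DLM constrains the per-lag log-odds effects of a repeatedly measured
binary exposure to a fractional polynomial of the lag,
``f(t) = delta_0 + delta_1 t + delta_2 t^2 + delta_3 sqrt(t)``, and fits
an ordinary logistic regression of the outcome on
``[intercept | W | covariates]`` where ``W`` is the collapsed 4-column
exposure design (see :mod:`fpdlm.basis`).  Point effects at any lag are
reconstructed as ``f_hat(t) = T(t)' delta_hat`` with delta-method
variance ``T(t)' Cov(delta_hat) T(t)``, giving an odds-ratio curve with
pointwise Wald confidence intervals, from which the critical window —
the maximal runs of lags with a significant effect — is read off.

Identifiability requires enough distinct lag values across subjects for
the basis columns of ``W`` to be of full rank: with exactly three shared
lags the four-term basis is rank 3 and the model is unidentifiable;
per-subject jitter in questionnaire response times is what rescues it in
real cohort data.  Fitting therefore refuses, with a named diagnostic,
when the design condition number exceeds 1e10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import DEFAULT_BASIS, FPBasis, build_collapsed_design
from .cohort import Cohort
from .glm import fit_logistic

__all__ = [
    "DLMFit",
    "LagEffect",
    "fit_dlm",
    "effect_at_lag",
    "effect_curve",
    "effects_to_frame",
    "detect_critical_windows",
]

Z975 = stats.norm.ppf(0.975)  # 1.959964

#: condition number above which the [W|Z] design is declared unidentifiable
CONDITION_LIMIT = 1e10


@dataclass
class LagEffect:
    """The lag-effect curve evaluated at one lag ``t``.

    ``beta_hat`` is the log-odds effect ``f_hat(t)``, ``se`` its
    delta-method standard error, ``or_`` the odds ratio and
    ``(ci_low, ci_high)`` the two-sided Wald confidence interval on the
    odds-ratio scale.  ``significant`` flags intervals excluding 1.
    """

    t: float
    beta_hat: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class DLMFit:
    """Fitted DLM: intercept, constraint coefficients and their covariance.

    ``delta`` holds the fractional-polynomial coefficients
    (delta_0..delta_3 for the default basis) and ``cov_delta`` the
    corresponding block of the inverse observed information.  ``eta``
    holds the covariate coefficients, named by dummy column.
    """

    intercept: float
    delta: np.ndarray
    eta: pd.Series
    cov_delta: np.ndarray
    basis: FPBasis
    converged: bool
    n_obs: int
    n_iter: int
    lag_min: float
    lag_max: float
    message: str = ""

    def default_grid(self) -> np.ndarray:
        """Integer lags spanning the observed lag range."""
        return np.arange(np.ceil(self.lag_min), np.floor(self.lag_max) + 1)


def _check_identifiable(design: np.ndarray, names: list[str]) -> None:
    """Refuse near-singular [W|Z] designs with an actionable message."""
    # scale columns to unit norm first so the check reflects collinearity,
    # not the wildly different magnitudes of t and t^2 columns
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0):
        dead = [names[j] for j in np.flatnonzero(norms == 0)]
        raise ValueError(
            f"degenerate design: column(s) {', '.join(dead)} are identically zero "
            "(e.g. no subject is exposed at any wave)"
        )
    scaled = design / norms
    s = np.linalg.svd(scaled, compute_uv=False)
    cond = s[0] / s[-1] if s[-1] > 0 else np.inf
    if cond > CONDITION_LIMIT:
        _, _, Vt = np.linalg.svd(scaled)
        load = np.abs(Vt[-1])
        worst = [names[j] for j in np.argsort(load)[::-1][:4] if load[j] > 0.1]
        raise ValueError(
            f"unidentifiable design (condition number {cond:.2e} > {CONDITION_LIMIT:.0e}); "
            f"near-collinear columns: {', '.join(worst)}. With only 3 distinct lags the "
            "4-term fractional-polynomial basis has rank 3; per-subject lag variation "
            "(jittered response times) is required, or use a smaller basis."
        )


def fit_dlm(
    cohort: Cohort,
    basis: FPBasis = DEFAULT_BASIS,
    *,
    include_covariates: bool = True,
) -> DLMFit:
    """Fit the fractional-polynomial DLM to a cohort by logistic MLE.

    The design is ``[intercept | W | encoded covariates]``; ``W`` is
    internally rescaled column-wise for numerical stability and the
    coefficients and covariance are mapped back to the raw basis scale.

    Raises
    ------
    ValueError
        If the design is unidentifiable (condition number above 1e10) or
        degenerate (all-zero exposure), naming the offending columns.
    """
    W = build_collapsed_design(cohort.exposures, cohort.lags, basis)
    names = [f"W[{nm}]" for nm in basis.names()]
    if include_covariates:
        Z = cohort.encoded_covariates()
    else:
        Z = pd.DataFrame(index=range(cohort.n))
    znames = list(Z.columns)
    full = np.column_stack([W, Z.to_numpy(dtype=float)]) if znames else W
    _check_identifiable(full, names + znames)

    # exact column rescaling: fit on W/s, then delta = delta_scaled / s
    s = np.abs(W).max(axis=0)
    s[s == 0] = 1.0
    design = np.column_stack([np.ones(cohort.n), W / s, Z.to_numpy(dtype=float)]) \
        if znames else np.column_stack([np.ones(cohort.n), W / s])
    res = fit_logistic(design, cohort.y)

    B = basis.size
    scale = np.concatenate([[1.0], 1.0 / s, np.ones(len(znames))])
    params = res.params * scale
    cov = res.cov * np.outer(scale, scale)
    return DLMFit(
        intercept=float(params[0]),
        delta=params[1 : 1 + B],
        eta=pd.Series(params[1 + B :], index=znames, dtype=float),
        cov_delta=cov[1 : 1 + B, 1 : 1 + B],
        basis=basis,
        converged=res.converged,
        n_obs=cohort.n,
        n_iter=res.n_iter,
        lag_min=float(cohort.lags.min()),
        lag_max=float(cohort.lags.max()),
        message=res.message,
    )


def effect_at_lag(fit: DLMFit, t: float, alpha: float = 0.05) -> LagEffect:
    """Reconstruct the lag effect ``f_hat(t)`` with delta-method variance.

    ``beta_hat = T(t)' delta_hat`` and
    ``V(f_hat(t)) = T(t)' Cov(delta_hat) T(t)`` with
    ``T(t) = (1, t, t^2, sqrt(t))`` for the default basis; the Wald
    interval is ``exp(beta_hat ± z_{1-alpha/2} se)``.
    """
    if not fit.converged:
        raise ValueError(f"cannot evaluate effects: fit did not converge ({fit.message})")
    T = fit.basis(float(t))
    beta = float(T @ fit.delta)
    var = float(T @ fit.cov_delta @ T)
    if var < 0 and var > -1e-12:  # clip tiny negative round-off
        var = 0.0
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(beta - z * se), np.exp(beta + z * se)
    if not np.isfinite(beta) or not np.isfinite(se):
        raise ValueError(f"non-finite effect at lag {t}")
    return LagEffect(
        t=float(t),
        beta_hat=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(se > 0 and abs(beta) / se > z),
    )


def effect_curve(fit: DLMFit, grid=None, alpha: float = 0.05) -> list[LagEffect]:
    """Evaluate the odds-ratio curve on a grid of lags (default: integer
    lags spanning the observed lag range), preserving grid order."""
    if grid is None:
        grid = fit.default_grid()
    return [effect_at_lag(fit, t, alpha) for t in np.asarray(grid, dtype=float)]


def effects_to_frame(effects: list[LagEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lag": [e.t for e in effects],
            "beta_hat": [e.beta_hat for e in effects],
            "se": [e.se for e in effects],
            "or": [e.or_ for e in effects],
            "ci_low": [e.ci_low for e in effects],
            "ci_high": [e.ci_high for e in effects],
            "significant": [e.significant for e in effects],
        }
    )


def detect_critical_windows(effects: list[LagEffect]) -> list[tuple[float, float]]:
    """Maximal runs of consecutive significant grid lags.

    Each window is reported as ``(first_lag, last_lag)``; a single
    significant lag gives a width-zero window.  Effects are assumed to
    lie on a sorted grid.
    """
    windows: list[tuple[float, float]] = []
    start: float | None = None
    prev: float | None = None
    for e in effects:
        if e.significant:
            if start is None:
                start = e.t
            prev = e.t
        else:
            if start is not None:
                windows.append((start, prev))
                start = None
    if start is not None:
        windows.append((start, prev))
    return windows
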