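"""Shared logistic maximum-likelihood engine.

Thin wrapper around :class:`statsmodels.api.Logit` used by every model in
the package (per-wave fits, the simultaneous fit and the DLM).  Newton /
IRLS with a relative log-likelihood tolerance of 1e-10 and at most 100
iterations; non-convergence (including perfect separation and a singular
information matrix) is a reported state, never a silent estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = ["LogisticFit", "fit_logistic"]


@dataclass
class LogisticFit:
    """MLE result of a logistic regression.

    ``cov`` is the inverse observed information evaluated at the MLE.
    When ``converged`` is False, ``params``/``cov`` may be NaN and must
    not be interpreted.
    """

    params: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    message: str = ""

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    *,
    add_intercept: bool = False,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> LogisticFit:
    """Fit a logistic regression by Newton's method.

    The caller supplies the full design matrix; with
    ``add_intercept=True`` a leading column of ones is prepended.
    Perfect separation or a singular information matrix yields a
    ``LogisticFit`` with ``converged=False`` and a diagnostic message.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"design has {X.shape[0]} rows but outcome has {y.shape[0]}")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    p = X.shape[1]
    nan = np.full(p, np.nan)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
        cov = np.asarray(res.cov_params())
        converged = bool(res.mle_retvals.get("converged", False)) and np.all(
            np.isfinite(res.params)
        ) and np.all(np.isfinite(cov))
        return LogisticFit(
            params=np.asarray(res.params),
            cov=cov,
            converged=converged,
            n_iter=int(res.mle_retvals.get("iterations", -1)),
            n_obs=X.shape[0],
            message="" if converged else "Newton iteration did not converge",
        )
    except PerfectSeparationError:
        return LogisticFit(nan, np.full((p, p), np.nan), False, 0, X.shape[0],
                           "perfect separation: MLE does not exist")
    except np.linalg.LinAlgError as err:
        return LogisticFit(nan, np.full((p, p), np.nan), False, 0, X.shape[0],
                           f"singular information matrix: {err}")
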