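"""Baseline analyses for time-varying binary exposure.

Single model: the exposure at each wave enters its own adjusted logistic
regression, one fit per wave.  Multi model: all K wave exposures enter
one logistic regression simultaneously.  With highly persistent
exposures the Single model absorbs the effects of the other waves
(bias away from the null) while the Multi model suffers variance
inflation from multicollinearity; the DLM in :mod:`fpdlm.dlm` trades a
smoothness constraint against both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .glm import fit_logistic

__all__ = ["PerLagEstimate", "fit_single", "fit_multi", "estimates_to_frame"]


@dataclass
class PerLagEstimate:
    """One wave's exposure coefficient from a Single or Multi fit."""

    canonical_time: float
    model: str  # "single" | "multi" | "dlm"
    beta_hat: float
    se: float
    converged: bool = True

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta_hat))

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return float(np.exp(self.beta_hat - z * self.se)), float(
            np.exp(self.beta_hat + z * self.se)
        )


def _times(cohort: Cohort, times) -> np.ndarray:
    if times is None:
        return cohort.nominal_lags()
    times = np.asarray(times, dtype=float)
    if times.shape[0] != cohort.K:
        raise ValueError("one canonical time per exposure wave is required")
    return times


def fit_single(
    cohort: Cohort,
    *,
    times=None,
    include_covariates: bool = True,
) -> list[PerLagEstimate]:
    """Fit K separate logistic regressions, one per exposure wave.

    Each fit regresses the outcome on ``[intercept | X_k | covariates]``.
    ``times`` labels the estimates (default: the per-wave modal lag).
    Convergence failures are reported per wave via ``converged``.
    """
    times = _times(cohort, times)
    Z = cohort.encoded_covariates().to_numpy(dtype=float) if include_covariates else None
    out = []
    for k in range(cohort.K):
        cols = [cohort.exposures[:, k].astype(float)]
        design = np.column_stack(cols + ([Z] if Z is not None and Z.size else []))
        res = fit_logistic(design, cohort.y, add_intercept=True)
        out.append(
            PerLagEstimate(
                canonical_time=float(times[k]),
                model="single",
                beta_hat=float(res.params[1]),
                se=float(res.se()[1]),
                converged=res.converged,
            )
        )
    return out


def fit_multi(
    cohort: Cohort,
    *,
    times=None,
    include_covariates: bool = True,
) -> list[PerLagEstimate]:
    """Fit one logistic regression with all K wave exposures entered jointly.

    Raises
    ------
    ValueError
        If the exposure columns are perfectly collinear (singular design).
    """
    times = _times(cohort, times)
    X = cohort.exposures.astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(cohort.n), X]))
    if rank < cohort.K + 1:
        raise ValueError(
            "singular design: exposure columns are perfectly collinear "
            f"(rank {rank} < {cohort.K + 1}); the simultaneous model is not identifiable"
        )
    Z = cohort.encoded_covariates().to_numpy(dtype=float) if include_covariates else None
    design = np.column_stack([X] + ([Z] if Z is not None and Z.size else []))
    res = fit_logistic(design, cohort.y, add_intercept=True)
    se = res.se()
    return [
        PerLagEstimate(
            canonical_time=float(times[k]),
            model="multi",
            beta_hat=float(res.params[1 + k]),
            se=float(se[1 + k]),
            converged=res.converged,
        )
        for k in range(cohort.K)
    ]


def estimates_to_frame(estimates: list[PerLagEstimate], alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for e in estimates:
        lo, hi = e.ci(alpha)
        rows.append(
            {
                "model": e.model,
                "time": e.canonical_time,
                "beta_hat": e.beta_hat,
                "se": e.se,
                "or": e.or_,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
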