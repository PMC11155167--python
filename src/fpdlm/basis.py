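"""Fractional-polynomial lag basis and the collapsed exposure design.

A distributed lag model (DLM) for a binary outcome constrains the
lag-specific log-odds effect beta(t) of a time-varying exposure to a
smooth function of the lag t (months before the outcome assessment).
Here the smooth function is a fractional polynomial

    f(t) = delta_0 + delta_1 * t + delta_2 * t**2 + delta_3 * sqrt(t),

so the regressors contributed by exposure indicators X_k observed at
per-subject lags t_k collapse into a single 4-column design row

    W = sum_k (1, t_k, t_k**2, sqrt(t_k)) * X_k,

turning the constrained DLM into an ordinary logistic regression on W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FPBasis", "DEFAULT_BASIS", "build_fp_basis", "build_collapsed_design"]


@dataclass(frozen=True)
class FPBasis:
    """A fractional-polynomial basis in the lag t, defined by its powers.

    Power 0 denotes the constant term. The default, ``(0, 1, 2, 0.5)``,
    is the four-term basis (1, t, t^2, sqrt(t)).
    """

    powers: tuple[float, ...] = (0.0, 1.0, 2.0, 0.5)

    @property
    def size(self) -> int:
        return len(self.powers)

    def __call__(self, t):
        """Evaluate the basis at lag(s) ``t``.

        Parameters
        ----------
        t : float or array-like
            Strictly positive lag(s) in months.

        Returns
        -------
        ndarray
            Shape ``t.shape + (size,)``; for scalar ``t`` a 1-d vector.
        """
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("lags must be finite and strictly positive")
        return np.stack([t**p for p in self.powers], axis=-1)

    def names(self) -> list[str]:
        out = []
        for p in self.powers:
            if p == 0:
                out.append("1")
            elif p == 1:
                out.append("t")
            elif p == int(p):
                out.append(f"t^{int(p)}")
            elif p == 0.5:
                out.append("sqrt(t)")
            else:
                out.append(f"t^{p}")
        return out


DEFAULT_BASIS = FPBasis()


def build_fp_basis(t: float, basis: FPBasis = DEFAULT_BASIS) -> np.ndarray:
    """Return the fractional-polynomial regressor vector at one lag.

    For the default basis this is ``(1, t, t**2, sqrt(t))``.

    Raises
    ------
    ValueError
        If ``t`` is non-positive or non-finite.
    """
    return basis(float(t))


def build_collapsed_design(
    exposures: np.ndarray,
    lags: np.ndarray,
    basis: FPBasis = DEFAULT_BASIS,
) -> np.ndarray:
    """Collapse per-lag binary exposures into the DLM design matrix W.

    Row i is ``sum_k basis(lags[i, k]) * exposures[i, k]``; the number of
    columns equals the basis size regardless of the number of exposure
    waves K.  A subject with no exposed waves gets an all-zero row, and
    the constant-basis column counts the exposed waves.

    Parameters
    ----------
    exposures : (n, K) array of {0, 1}
    lags : (n, K) array of strictly positive months
    """
    exposures = np.asarray(exposures, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if exposures.ndim == 1:
        exposures = exposures[None, :]
    if lags.ndim == 1:
        lags = lags[None, :]
    if exposures.shape != lags.shape:
        raise ValueError(
            f"exposures {exposures.shape} and lags {lags.shape} must share one (n, K) shape"
        )
    if not np.isin(exposures, (0.0, 1.0)).all():
        raise ValueError("exposures must be binary 0/1")
    B = basis(lags)  # (n, K, size)
    return np.einsum("nkb,nk->nb", B, exposures)
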