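"""Cohort data container and CSV interchange.

A cohort is one row per subject: a binary outcome ``y``, K binary
exposure indicators ``x1..xK``, K strictly positive per-subject lags
``lag1..lagK`` (months before the outcome assessment, ordered most
recent wave first), and optional categorical covariates.  The CSV
dialect mirrors these columns plus an ``id`` column; comma-separated,
``.`` decimal, header mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Cohort", "encode_covariates"]


def encode_covariates(covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Reference-cell (dummy) encode categorical covariates.

    The reference level is the first category in the declared category
    order (for plain object columns: first level in sorted order, the
    pandas Categorical default).
    """
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=covariates.index if covariates is not None else None)
    enc = pd.get_dummies(covariates.astype("category"), drop_first=True, dtype=float)
    return enc


@dataclass
class Cohort:
    """In-memory cohort: outcome, exposure waves, per-subject lags, covariates."""

    y: np.ndarray
    exposures: np.ndarray
    lags: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int).ravel()
        self.exposures = np.atleast_2d(np.asarray(self.exposures, dtype=int))
        self.lags = np.atleast_2d(np.asarray(self.lags, dtype=float))
        n = self.y.shape[0]
        if self.exposures.shape[0] != n or self.lags.shape[0] != n:
            raise ValueError("outcome, exposures and lags must have one row per subject")
        if self.exposures.shape != self.lags.shape:
            raise ValueError(
                f"exposures {self.exposures.shape} and lags {self.lags.shape} differ in shape"
            )
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcome must be binary 0/1")
        if not np.isin(self.exposures, (0, 1)).all():
            raise ValueError("exposure indicators must be binary 0/1")
        if not (np.isfinite(self.lags).all() and (self.lags > 0).all()):
            raise ValueError("lags must be finite and strictly positive months")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariates must have one row per subject")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def K(self) -> int:
        return self.exposures.shape[1]

    def nominal_lags(self) -> np.ndarray:
        """Per-wave modal lag (the canonical questionnaire time)."""
        out = np.empty(self.K)
        for k in range(self.K):
            vals, counts = np.unique(self.lags[:, k], return_counts=True)
            out[k] = vals[np.argmax(counts)]
        return out

    def lag_range(self) -> tuple[float, float]:
        return float(self.lags.min()), float(self.lags.max())

    def encoded_covariates(self) -> pd.DataFrame:
        return encode_covariates(self.covariates)

    # -- CSV interchange ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        K = self.K
        data: dict[str, object] = {"id": np.arange(1, self.n + 1), "y": self.y}
        for k in range(K):
            data[f"x{k + 1}"] = self.exposures[:, k]
        for k in range(K):
            data[f"lag{k + 1}"] = np.round(self.lags[:, k], 1)
        frame = pd.DataFrame(data)
        if self.covariates is not None:
            for col in self.covariates.columns:
                frame[col] = self.covariates[col].to_numpy()
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        cols = set(frame.columns)
        if "y" not in cols:
            raise ValueError("cohort CSV is missing the outcome column 'y'")
        K = 0
        while f"x{K + 1}" in cols:
            K += 1
        if K == 0:
            raise ValueError("cohort CSV has no exposure columns 'x1..xK'")
        missing = [f"lag{k + 1}" for k in range(K) if f"lag{k + 1}" not in cols]
        if missing:
            raise ValueError(f"cohort CSV is missing lag columns: {', '.join(missing)}")
        xcols = [f"x{k + 1}" for k in range(K)]
        lcols = [f"lag{k + 1}" for k in range(K)]
        covcols = [c for c in frame.columns if c not in {"id", "y", *xcols, *lcols}]
        cov = frame[covcols].copy() if covcols else None
        return cls(
            y=frame["y"].to_numpy(),
            exposures=frame[xcols].to_numpy(),
            lags=frame[lcols].to_numpy(),
            covariates=cov,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path))
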