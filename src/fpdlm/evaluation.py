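"""Replication runner and simulation performance metrics.

For each replication a fresh dataset is generated and each requested
model is fitted; estimates are recorded at the canonical questionnaire
times 6k (k = 1..10): the k-th exposure coefficient for the Single and
Multi models, and the reconstructed lag effect f_hat(6k) for the DLM.
Across replications the metrics are

    bias   = mean(beta_hat) - beta(6k)
    EmpSE  = sample SD of beta_hat        (n-1 denominator)
    MSE    = mean((beta_hat - beta(6k))**2)

reported both raw and on the x100 display scale.  Replications whose
fit fails to converge are counted and excluded, never silently retried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparators, dlm as dlm_mod
from .simulate import Scenario, generate_dataset

__all__ = ["ReplicationResult", "PerformanceTable", "run_replications", "compute_metrics", "write_tables"]

MODELS = ("single", "multi", "dlm")
METRICS = ("bias", "empse", "mse")


@dataclass
class ReplicationResult:
    """Per-replication estimates at the canonical times, per model."""

    rep_id: int
    model: str
    estimates: dict[float, float]
    converged: bool


@dataclass
class PerformanceTable:
    """Tidy per-cell metrics with replication bookkeeping."""

    cells: pd.DataFrame  # columns: scenario, gamma, time, model, metric, value_raw, value_x100
    n_reps: int
    n_failed: dict[str, int]

    def value(self, metric: str, model: str, time: float, x100: bool = True) -> float:
        sel = self.cells[
            (self.cells["metric"] == metric)
            & (self.cells["model"] == model)
            & (self.cells["time"] == time)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique cell for ({metric}, {model}, {time})")
        return float(sel["value_x100" if x100 else "value_raw"].iloc[0])


def _rep_seed_rng(master_seed: int, rep_id: int) -> np.random.Generator:
    # counter-based substream: any replication is re-runnable in isolation
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(rep_id,)))


def run_replications(
    scenario: Scenario,
    gamma: float,
    n: int = 10000,
    reps: int = 1000,
    models: tuple[str, ...] = MODELS,
    master_seed: int = 0,
    K: int = 10,
) -> list[ReplicationResult]:
    """Run the simulation study for one (scenario, gamma) condition.

    Deterministic given ``master_seed``; per-replication substreams are
    derived from it by counter so results do not depend on which models
    are requested.
    """
    if reps < 2:
        raise ValueError("at least 2 replications are required")
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    canonical = [6.0 * k for k in range(1, K + 1)]
    results: list[ReplicationResult] = []
    for rep in range(reps):
        rng = _rep_seed_rng(master_seed, rep)
        ds = generate_dataset(scenario, gamma, n=n, K=K, rng=rng)
        cohort = ds.to_cohort()
        if "single" in models:
            ests = comparators.fit_single(cohort, times=canonical, include_covariates=False)
            results.append(
                ReplicationResult(
                    rep, "single",
                    {e.canonical_time: e.beta_hat for e in ests},
                    all(e.converged for e in ests),
                )
            )
        if "multi" in models:
            ests = comparators.fit_multi(cohort, times=canonical, include_covariates=False)
            results.append(
                ReplicationResult(
                    rep, "multi",
                    {e.canonical_time: e.beta_hat for e in ests},
                    all(e.converged for e in ests),
                )
            )
        if "dlm" in models:
            fit = dlm_mod.fit_dlm(cohort)
            if fit.converged:
                effects = {t: dlm_mod.effect_at_lag(fit, t).beta_hat for t in canonical}
            else:
                effects = {}
            results.append(ReplicationResult(rep, "dlm", effects, fit.converged))
    return results


def compute_metrics(
    results: list[ReplicationResult],
    scenario: Scenario,
    gamma: float | None = None,
) -> PerformanceTable:
    """Aggregate replication estimates into bias / EmpSE / MSE cells."""
    by_model: dict[str, list[ReplicationResult]] = {}
    for r in results:
        by_model.setdefault(r.model, []).append(r)
    n_reps = max(len(v) for v in by_model.values())
    rows = []
    n_failed = {}
    for model, reps_list in by_model.items():
        ok = [r for r in reps_list if r.converged]
        n_failed[model] = len(reps_list) - len(ok)
        if not ok:
            raise ValueError(f"no converged replications for model '{model}'")
        if n_failed[model] > 0.01 * len(reps_list):
            warnings.warn(
                f"{n_failed[model]}/{len(reps_list)} replications failed for '{model}'",
                stacklevel=2,
            )
        times = sorted(ok[0].estimates)
        est = np.array([[r.estimates[t] for t in times] for r in ok])
        truth = scenario.true_effect(np.asarray(times))
        bias = est.mean(axis=0) - truth
        empse = est.std(axis=0, ddof=1)
        mse = ((est - truth) ** 2).mean(axis=0)
        for j, t in enumerate(times):
            for metric, val in (("bias", bias[j]), ("empse", empse[j]), ("mse", mse[j])):
                rows.append(
                    {
                        "scenario": scenario.id,
                        "gamma": gamma,
                        "time": t,
                        "model": model,
                        "metric": metric,
                        "value_raw": val,
                        "value_x100": 100.0 * val,
                    }
                )
    cells = pd.DataFrame(rows).sort_values(
        ["scenario", "gamma", "time", "model", "metric"], kind="stable"
    ).reset_index(drop=True)
    return PerformanceTable(cells=cells, n_reps=n_reps, n_failed=n_failed)


def write_tables(table: PerformanceTable, out_dir) -> dict[str, str]:
    """Write one tidy CSV per metric (bias, empse, mse).

    Rows are ordered by (scenario, gamma, time, model); columns are
    ``scenario, gamma, time, model, value_raw, value_x100``.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for metric in METRICS:
        sub = table.cells[table.cells["metric"] == metric].drop(columns="metric")
        sub = sub.sort_values(["scenario", "gamma", "time", "model"], kind="stable")
        path = out / f"{metric}.csv"
        sub.to_csv(path, index=False)
        paths[metric] = str(path)
    return paths
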