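"""The fractional-polynomial DLM: fitting, effect reconstruction, windows."""

import numpy as np
import pytest

from fpdlm import (
    Cohort,
    DLMFit,
    FPBasis,
    LagEffect,
    detect_critical_windows,
    effect_at_lag,
    effect_curve,
    fit_dlm,
    fit_logistic,
    fit_multi,
)
from fpdlm.basis import DEFAULT_BASIS


def _manual_fit(delta, cov, basis=DEFAULT_BASIS):
    return DLMFit(
        intercept=-2.0,
        delta=np.asarray(delta, dtype=float),
        eta=__import__("pandas").Series(dtype=float),
        cov_delta=np.asarray(cov, dtype=float),
        basis=basis,
        converged=True,
        n_obs=1000,
        n_iter=5,
        lag_min=6.0,
        lag_max=60.0,
    )


# ---------------------------------------------------------------- fitting


def test_delta_recovery_constant_effect(sim_dataset_s1):
    """Scenario-1 data carry delta = (0.15, 0, 0, 0); the fit recovers it."""
    fit = fit_dlm(sim_dataset_s1.to_cohort())
    assert fit.converged
    truth = np.array([0.15, 0.0, 0.0, 0.0])
    se = np.sqrt(np.diag(fit.cov_delta))
    assert np.all(np.abs(fit.delta - truth) < 3 * se)
    assert np.allclose(fit.cov_delta, fit.cov_delta.T, atol=1e-12)
    assert np.all(np.diag(fit.cov_delta) >= 0)


def test_reduction_to_exposure_count_regression(sim_dataset_s1):
    """Constant-only basis makes the DLM a logistic fit on the exposure count."""
    cohort = sim_dataset_s1.to_cohort()
    fit = fit_dlm(cohort, basis=FPBasis(powers=(0.0,)))
    count = cohort.exposures.sum(axis=1).astype(float)
    ref = fit_logistic(count[:, None], cohort.y, add_intercept=True)
    assert np.isclose(fit.delta[0], ref.params[1], atol=1e-8)
    assert np.isclose(fit.intercept, ref.params[0], atol=1e-8)


def test_saturated_basis_reproduces_multi_model(rng):
    """With K shared lags and a K-term basis the DLM is the Multi model."""
    n = 5000
    X = (rng.random((n, 3)) < 0.25).astype(int)
    lags = np.tile([18.0, 30.0, 39.0], (n, 1))
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + X @ [0.3, 0.1, -0.2])))).astype(int)
    cohort = Cohort(y=y, exposures=X, lags=lags)
    fit = fit_dlm(cohort, basis=FPBasis(powers=(0.0, 1.0, 2.0)))
    multi = fit_multi(cohort, times=[18.0, 30.0, 39.0])
    for est in multi:
        eff = effect_at_lag(fit, est.canonical_time)
        assert np.isclose(eff.beta_hat, est.beta_hat, atol=1e-6)
        assert np.isclose(eff.se, est.se, rtol=1e-4)


def test_three_shared_lags_are_rank_deficient_for_four_term_basis(rng):
    n = 2000
    X = (rng.random((n, 3)) < 0.3).astype(int)
    lags = np.tile([18.0, 30.0, 39.0], (n, 1))
    y = rng.integers(0, 2, n)
    with pytest.raises(ValueError, match="unidentifiable|condition"):
        fit_dlm(Cohort(y=y, exposures=X, lags=lags))


def test_all_zero_exposures_is_degenerate(rng):
    n = 500
    cohort = Cohort(
        y=rng.integers(0, 2, n),
        exposures=np.zeros((n, 3), dtype=int),
        lags=np.tile([18.0, 30.0, 39.0], (n, 1)),
    )
    with pytest.raises(ValueError, match="zero|degenerate"):
        fit_dlm(cohort)


# ------------------------------------------------- effect reconstruction


def test_constant_delta_gives_flat_curve():
    fit = _manual_fit([0.15, 0, 0, 0], np.diag([1e-4, 0, 0, 0]))
    for t in (6.0, 24.0, 60.0):
        assert np.isclose(effect_at_lag(fit, t).beta_hat, 0.15)


def test_null_delta_gives_unit_odds_ratio():
    cov = np.diag([1e-4, 1e-8, 1e-12, 1e-6])
    fit = _manual_fit(np.zeros(4), cov)
    eff = effect_at_lag(fit, 30.0)
    assert eff.or_ == 1.0
    assert not eff.significant
    # Wald interval is symmetric about 1 on the log scale
    assert np.isclose(eff.ci_low * eff.ci_high, 1.0, rtol=1e-10)


def test_delta_method_se_matches_monte_carlo_oracle(sim_dataset_s1):
    """T' Cov T agrees with the SD of T'd over 1e6 MVN draws within 1%."""
    fit = fit_dlm(sim_dataset_s1.to_cohort())
    rng = np.random.default_rng(99)
    draws = rng.multivariate_normal(fit.delta, fit.cov_delta, size=10**6, method="cholesky")
    for t in (8.0, 24.0, 47.0):
        T = fit.basis(t)
        mc_sd = (draws @ T).std(ddof=1)
        assert np.isclose(effect_at_lag(fit, t).se, mc_sd, rtol=0.01)


def test_variance_nonnegative_across_grid(sim_dataset_s1):
    fit = fit_dlm(sim_dataset_s1.to_cohort())
    for eff in effect_curve(fit, np.linspace(1.0, 80.0, 120)):
        assert eff.se >= 0.0


def test_effect_curve_preserves_grid_and_handles_empty(sim_dataset_s1):
    fit = fit_dlm(sim_dataset_s1.to_cohort())
    grid = [6.0, 12.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0, 54.0, 60.0]
    effs = effect_curve(fit, grid)
    assert [e.t for e in effs] == grid
    assert effect_curve(fit, []) == []
    flat = _manual_fit([0.15, 0, 0, 0], np.diag([1e-4, 0, 0, 0]))
    betas = {e.beta_hat for e in effect_curve(flat, grid)}
    assert len(betas) == 1


def test_effect_at_lag_requires_convergence():
    fit = _manual_fit(np.zeros(4), np.eye(4))
    fit.converged = False
    with pytest.raises(ValueError, match="converge"):
        effect_at_lag(fit, 24.0)


# ------------------------------------------------------- window detection


def _effects(lags, flags):
    return [
        LagEffect(t=t, beta_hat=0.1, se=0.01, or_=1.1, ci_low=1.05, ci_high=1.2, significant=f)
        for t, f in zip(lags, flags)
    ]


@pytest.mark.parametrize(
    "lags, flags, expected",
    [
        ([28, 29, 30, 31, 32, 33], [False, False, True, True, True, False], [(30, 32)]),
        ([6, 12, 18], [False, False, False], []),
        ([10, 11, 12], [True, False, True], [(10, 10), (12, 12)]),
        ([], [], []),
        ([40, 41], [True, True], [(40, 41)]),
    ],
)
def test_detect_critical_windows_patterns(lags, flags, expected):
    assert detect_critical_windows(_effects(lags, flags)) == expected
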