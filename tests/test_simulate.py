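"""The correlated-binary exposure simulator and scenario machinery."""

import numpy as np
import pytest
from scipy import stats

from fpdlm import (
    ar1_correlation,
    generate_dataset,
    make_scenario,
    sample_correlated_binary,
    sample_times,
    simulate_outcomes,
)
from fpdlm.simulate import TIME_JITTER_OFFSETS, TIME_JITTER_PROBS


# ------------------------------------------------------------- AR(1)


def test_ar1_identity_at_zero():
    np.testing.assert_array_equal(ar1_correlation(0.0, 3), np.eye(3))


def test_ar1_powers():
    C = ar1_correlation(0.5, 3)
    assert C[0, 2] == 0.25
    C2 = ar1_correlation(0.975, 2)
    assert C2[0, 1] == 0.975
    assert np.all(np.diag(C2) == 1.0)


@pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
def test_ar1_domain(bad):
    with pytest.raises(ValueError):
        ar1_correlation(bad, 3)


# ----------------------------------------------------------- times


def test_time_support_and_frequencies(rng):
    t = sample_times(10, 10**6, rng)
    assert np.all(t > 0)
    assert set(np.unique(t[:, 0])) == {4, 5, 6, 7, 8, 9}
    # modal point of wave 5 sits at 30 with probability 0.45
    frac30 = np.mean(t[:, 4] == 30)
    assert abs(frac30 - 0.45) < 0.002
    # chi-squared goodness of fit of wave 1 to the printed law
    counts = np.array([(t[:, 0] == 6 + off).sum() for off in TIME_JITTER_OFFSETS])
    stat, p = stats.chisquare(counts, f_exp=TIME_JITTER_PROBS * 10**6)
    assert p > 1e-3


# ----------------------------------------------------------- copula


def test_marginals_are_calibrated(rng):
    C = ar1_correlation(0.975, 10)
    X = sample_correlated_binary(C, 0.2, 10**5, rng)
    assert np.all(np.abs(X.mean(axis=0) - 0.2) < 0.005)


def test_joint_probability_matches_bivariate_normal_orthant(rng):
    """K=2: P(X1=1, X2=1) equals the orthant mass Phi2(g(p), g(p); gamma)."""
    gamma, p, n = 0.6, 0.2, 4 * 10**5
    X = sample_correlated_binary(ar1_correlation(gamma, 2), p, n, rng)
    emp = np.mean((X[:, 0] == 1) & (X[:, 1] == 1))
    g = stats.norm.ppf(p)
    oracle = stats.multivariate_normal(
        mean=[0, 0], cov=[[1, gamma], [gamma, 1]]
    ).cdf([g, g])
    assert abs(emp - oracle) < 4 * np.sqrt(oracle * (1 - oracle) / n)


def test_agreement_monotone_in_gamma(rng):
    agree = []
    for gamma in (0.0, 0.5, 0.975, 0.9999):
        X = sample_correlated_binary(ar1_correlation(gamma, 2), 0.2, 10**5, rng)
        agree.append(np.mean(X[:, 0] == X[:, 1]))
    assert all(a < b for a, b in zip(agree, agree[1:]))
    assert 1 - agree[-1] < 0.01  # near-perfect latent correlation


def test_copula_probability_domain():
    with pytest.raises(ValueError):
        sample_correlated_binary(np.eye(2), [0.2, 1.0], 10, np.random.default_rng(0))


# -------------------------------------------------------- scenarios


def test_scenario_curves():
    s1 = make_scenario(1)
    assert s1.true_effect(6.0) == 0.15 == s1.true_effect(60.0)
    s3 = make_scenario(3)
    assert s3.true_effect(35.9) == 0.0
    assert s3.true_effect(36.0) == 0.25
    assert s3.true_effect(47.0) == 0.25
    assert s3.true_effect(47.1) == 0.0
    s2 = make_scenario(2)
    grid = np.linspace(4.0, 63.0, 200)
    vals = s2.true_effect(grid)
    assert np.argmax(vals) == np.argmin(np.abs(grid - 33.0))
    assert np.all(vals > 0)  # effects always exist
    with pytest.raises(ValueError):
        make_scenario(4)


# --------------------------------------------------------- outcomes


def test_outcome_rates_closed_form(rng, scenario1):
    n = 10**6
    K = 10
    times = sample_times(K, n, rng)
    zero = np.zeros((n, K), dtype=int)
    y0 = simulate_outcomes(zero, times, scenario1, rng)
    base = 1 / (1 + np.exp(2.2))  # expit(-2.2) = 0.0998
    assert abs(y0.mean() - base) < 4 * np.sqrt(base * (1 - base) / n)

    ones = np.ones((200000, K), dtype=int)
    y1 = simulate_outcomes(ones, times[:200000], scenario1, rng)
    full = 1 / (1 + np.exp(0.7))  # expit(-2.2 + 10*0.15) = 0.3318
    assert abs(y1.mean() - full) < 4 * np.sqrt(full * (1 - full) / 200000)


def test_overall_prevalence_near_twelve_percent(rng, scenario1):
    """gamma=0, Scenario 1: prevalence of expit(-2.2 + 0.15 Bin(10, 0.2))."""
    ds = generate_dataset(scenario1, 0.0, n=2 * 10**5, seed=5)
    assert 0.115 < ds.outcomes.mean() < 0.135


# ---------------------------------------------------- dataset assembly


def test_generate_dataset_deterministic(scenario1):
    a = generate_dataset(scenario1, 0.975, n=2000, seed=11)
    b = generate_dataset(scenario1, 0.975, n=2000, seed=11)
    np.testing.assert_array_equal(a.exposures, b.exposures)
    np.testing.assert_array_equal(a.times, b.times)
    np.testing.assert_array_equal(a.outcomes, b.outcomes)


def test_independent_exposures_at_gamma_zero(scenario1):
    ds = generate_dataset(scenario1, 0.0, n=10**5, seed=3)
    corr = np.corrcoef(ds.exposures.T)
    off = corr[~np.eye(10, dtype=bool)]
    assert np.all(np.abs(off) < 0.015)
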