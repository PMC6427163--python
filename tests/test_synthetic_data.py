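"""Generator calibration, lag bookkeeping and noise-model checks."""

import numpy as np
import pytest

from pmgam import (
    CovariateSeries,
    HarmonicTrend,
    TrueModel,
    calibrate_intercept,
    default_true_model,
    generate_covariates,
    linear_predictor,
    simulate_deaths,
    simulate_series,
)
from pmgam.synthetic_data import (
    DEFAULT_CALIBRATION,
    GeneratorError,
    ParameterError,
    _pm25_raw_moments,
)


def test_lag_columns_are_exact_shifts(cov1096):
    lagmat = cov1096.lag_matrix(range(1, 8))
    # lag definition: pm25_lag[3][t] == pm25_lag[1][t-2]
    np.testing.assert_array_equal(lagmat[2:, 2], lagmat[:-2, 0])
    np.testing.assert_array_equal(lagmat[5:, 6], lagmat[:-5, 1])
    # same-day series in ug/m3 matches lag-1 shifted by one day
    np.testing.assert_allclose(lagmat[1:, 0] * 10.0, cov1096.pm25[:-1])


def test_pm25_marginal_matches_calibration_targets():
    big = generate_covariates(100_000, seed=2)
    assert 52.3 <= big.pm25.mean() <= 57.8
    assert 36.7 <= big.pm25.std(ddof=1) <= 40.5


def test_pm25_moment_matching_against_mc_oracle():
    """The analytic lognormal-AR moment matching agrees with a brute-force
    million-day Monte-Carlo estimate of the marginal mean and SD."""
    mc = generate_covariates(1_000_000, seed=5)
    assert abs(mc.pm25.mean() - DEFAULT_CALIBRATION.pm25_mean) < 0.02 * 55.0
    assert abs(mc.pm25.std(ddof=1) - DEFAULT_CALIBRATION.pm25_sd) < 0.03 * 38.6
    # and the raw-moment helper itself is internally consistent with MC
    raw_mean, raw_sd = _pm25_raw_moments(DEFAULT_CALIBRATION)
    assert raw_sd > 0 and raw_mean > 0


def test_pm25_is_autocorrelated_and_seasonal():
    cov = generate_covariates(1096, seed=11)
    x = np.log(cov.pm25)
    r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert r1 > 0.4  # day-to-day persistence
    t = cov.day_index
    winter = cov.pm25[np.cos(2 * np.pi * t / 365.25) > 0.5].mean()
    summer = cov.pm25[np.cos(2 * np.pi * t / 365.25) < -0.5].mean()
    assert winter > summer  # winter peak


def test_swt_is_seasonal_and_dow_cycles():
    cov = generate_covariates(1096, seed=3)
    t = cov.day_index
    cold = np.isin(cov.swt, [3, 6])
    winter_mask = np.cos(2 * np.pi * t / 365.25) > 0.5
    assert cold[winter_mask].mean() > cold[~winter_mask].mean()
    np.testing.assert_array_equal(cov.dow, (t - 1) % 7)


def test_seasonal_trend_amplitude_moment_matched():
    trend = HarmonicTrend.with_log_variance(0.075)
    grid = np.arange(1.0, 1462.0)  # four whole years
    assert abs(np.var(trend(grid)) - 0.075) < 0.02 * 0.075


def test_too_short_series_rejected():
    with pytest.raises(GeneratorError):
        generate_covariates(6, seed=0)


def _reference_covariates(n=30):
    return CovariateSeries(
        pm25=np.zeros(n),
        swt=np.ones(n, dtype=int),
        dow=np.zeros(n, dtype=int),
        pm25_history=np.zeros(7),
    )


def test_linear_predictor_at_reference_levels():
    """With all covariates at reference and no trend, the mean daily count
    is exp(beta0) for the raw (uncalibrated) truth."""
    model = default_true_model(seasonal_trend=lambda t: np.zeros_like(t))
    eta = linear_predictor(model, _reference_covariates())
    np.testing.assert_allclose(np.exp(eta), np.exp(3.9666423), rtol=1e-12)


def test_lag1_increase_multiplies_mean_by_exp_beta1():
    model = default_true_model(seasonal_trend=lambda t: np.zeros_like(t))
    cov = _reference_covariates()
    bumped = CovariateSeries(
        pm25=cov.pm25.copy(),
        swt=cov.swt,
        dow=cov.dow,
        pm25_history=np.array([0, 0, 0, 0, 0, 0, 10.0]),  # +10 ug/m3 the day before day 1
    )
    ratio = np.exp(linear_predictor(model, bumped) - linear_predictor(model, cov))
    np.testing.assert_allclose(ratio[0], np.exp(0.0049014), rtol=1e-12)  # lag 1
    np.testing.assert_allclose(ratio[1], np.exp(-0.0020338), rtol=1e-12)  # lag 2
    np.testing.assert_allclose(ratio[6], np.exp(-0.0004166), rtol=1e-12)  # lag 7
    np.testing.assert_allclose(ratio[7:], 1.0, rtol=1e-12)  # beyond max lag


def test_linear_predictor_matches_per_term_summation_oracle():
    rng = np.random.default_rng(9)
    model = TrueModel(
        beta0=rng.normal(),
        beta_lag=tuple(rng.normal(scale=0.01, size=7)),
        phi_swt=(0.0, *rng.normal(scale=0.05, size=5)),
        phi_dow=(0.0, *rng.normal(scale=0.02, size=6)),
        seasonal_trend=lambda t: 0.1 * np.sin(0.01 * np.asarray(t)),
        sigma_hat=0.3,
        gamma=0.2,
    )
    cov = generate_covariates(60, seed=4)
    eta = linear_predictor(model, cov)
    extended = np.concatenate([cov.pm25_history, cov.pm25])
    for i in range(cov.n_days):
        t = i + 1
        acc = model.beta0 + 0.1 * np.sin(0.01 * t)
        for lag in range(1, 8):
            acc += model.beta_lag[lag - 1] * extended[7 + i - lag] / 10.0
        acc += model.phi_swt[cov.swt[i] - 1] + model.phi_dow[cov.dow[i]]
        assert abs(eta[i] - acc) < 1e-12


def test_unknown_category_level_rejected():
    cov = _reference_covariates()
    with pytest.raises(GeneratorError):
        CovariateSeries(pm25=cov.pm25, swt=cov.swt * 7, dow=cov.dow)


def test_zero_gamma_reproduces_mean_exactly(mean_series, truth):
    sim = simulate_deaths(mean_series, 0.0, truth.sigma_hat, seed=123)
    np.testing.assert_array_equal(sim.deaths, mean_series)
    np.testing.assert_array_equal(sim.epsilon, 0.0)


def test_negative_gamma_rejected(mean_series):
    with pytest.raises(ParameterError):
        simulate_deaths(mean_series, -0.1, 0.34, seed=1)


def test_lognormal_mean_inflation_matches_mc_oracle():
    """E[deaths] = mean * exp(sigma^2 / 2), checked against 10^6 draws."""
    gamma, sigma_hat = 0.8, 0.34
    sigma = gamma * sigma_hat
    mean = np.full(1_000_000, 20.0)
    sim = simulate_deaths(mean, gamma, sigma_hat, seed=17)
    analytic = 20.0 * np.exp(sigma**2 / 2.0)
    se = 20.0 * np.sqrt((np.exp(sigma**2) - 1) * np.exp(sigma**2)) / 1000.0
    assert abs(sim.deaths.mean() - analytic) < 4 * se


def test_mean_daily_deaths_calibrated_to_observed_level(mean_series, truth):
    """Across 100 replicate series the mean daily count stays near 32."""
    means = [
        simulate_deaths(mean_series, 0.5, truth.sigma_hat, seed=100 + r).deaths.mean()
        for r in range(100)
    ]
    assert 30.0 <= np.mean(means) <= 34.0


def test_death_sd_nondecreasing_in_gamma(mean_series, truth):
    gammas = np.round(np.arange(0.1, 1.01, 0.1), 2)
    avg_sd = []
    for g in gammas:
        sds = [
            simulate_deaths(mean_series, g, truth.sigma_hat, seed=200 + r).deaths.std(ddof=1)
            for r in range(20)
        ]
        avg_sd.append(np.mean(sds))
    assert np.all(np.diff(avg_sd) >= 0)


def test_simulated_sd_near_real_scale_at_half_noise(sim_halfnoise):
    # the gamma = 0.5 noise level reproduces the observed daily-death SD (~11)
    assert 9.0 <= sim_halfnoise.deaths.std(ddof=1) <= 13.0


def test_simulate_series_reproducible(truth, cov1096):
    a = simulate_series(truth, cov1096, seed=5)
    b = simulate_series(truth, cov1096, seed=5)
    np.testing.assert_array_equal(a.deaths, b.deaths)


def test_intercept_calibration_hits_target(truth, cov1096):
    recal = calibrate_intercept(truth, cov1096, target_mean_deaths=40.0)
    mu = np.exp(linear_predictor(recal, cov1096))
    assert abs(mu.mean() - 40.0) < 1e-9
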