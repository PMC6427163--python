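"""MCMC sampler: closed-form, quadrature and summation oracles."""

import numpy as np
import pytest

from pmgam import GamSpec, McmcSettings, NormalPrior, PriorSpec
from pmgam import bayes_gam, freq_gam
from pmgam.bayes_gam import (
    PosteriorResult,
    adaptive_metropolis,
    log_posterior,
    sample_posterior,
    summarize_posterior,
)
from pmgam.synthetic_data import generate_covariates


@pytest.fixture(scope="module")
def toy_design(cov400, truth):
    from pmgam.synthetic_data import linear_predictor, simulate_deaths

    sim = simulate_deaths(
        np.exp(linear_predictor(truth, cov400)[: cov400.n_days]),
        0.5,
        truth.sigma_hat,
        seed=8,
    )
    return GamSpec(df_per_year=4.0).build(cov400, sim.deaths)


def test_flat_prior_log_posterior_reduces_to_likelihood(toy_design):
    rng = np.random.default_rng(0)
    p, sl = toy_design.n_parametric, toy_design.spline_slice
    q = sl.stop - sl.start
    th1, th2 = 0.01 * rng.normal(size=(2, p))
    th1[0] = th2[0] = 3.4
    b = 0.01 * rng.normal(size=q)
    flat = PriorSpec()
    # tau^2 -> infinity: posterior differences equal likelihood differences
    d_post = log_posterior(th1, b, toy_design, flat, np.inf) - log_posterior(
        th2, b, toy_design, flat, np.inf
    )
    eta1 = toy_design.X[:, :p] @ th1 + toy_design.X[:, sl] @ b
    eta2 = toy_design.X[:, :p] @ th2 + toy_design.X[:, sl] @ b
    d_lik = bayes_gam.poisson_loglik(toy_design.y, eta1) - bayes_gam.poisson_loglik(
        toy_design.y, eta2
    )
    assert abs(d_post - d_lik) < 1e-10


def test_normal_prior_contribution_is_gaussian_quadratic(toy_design):
    mu, V, s = 0.005, 0.004, 0.002
    priors = PriorSpec(coef_priors={"lag1": NormalPrior(mu, V)})
    p, sl = toy_design.n_parametric, toy_design.spline_slice
    j = toy_design.names.index("lag1")
    th = np.zeros(p)
    th[0] = 3.4
    b = np.zeros(sl.stop - sl.start)
    th_at = th.copy()
    th_at[j] = mu
    th_off = th.copy()
    th_off[j] = mu + s
    d_post = log_posterior(th_at, b, toy_design, priors, 1.0) - log_posterior(
        th_off, b, toy_design, priors, 1.0
    )
    flat = PriorSpec()
    d_lik = log_posterior(th_at, b, toy_design, flat, 1.0) - log_posterior(
        th_off, b, toy_design, flat, 1.0
    )
    # differences of ~1e1-magnitude log posteriors: allow float cancellation
    assert abs((d_post - d_lik) - s**2 / (2 * V)) < 1e-9


def test_log_posterior_matches_term_by_term_oracle(toy_design):
    rng = np.random.default_rng(1)
    p, sl = toy_design.n_parametric, toy_design.spline_slice
    q = sl.stop - sl.start
    th = 0.02 * rng.normal(size=p)
    th[0] = 3.3
    b = 0.05 * rng.normal(size=q)
    mu_p, V_p, tau2 = 0.005, 0.003, 0.7
    priors = PriorSpec(coef_priors={"lag1": NormalPrior(mu_p, V_p)})
    got = log_posterior(th, b, toy_design, priors, tau2)
    # explicit per-observation / per-term summation
    j = toy_design.names.index("lag1")
    expected = 0.0
    for i in range(toy_design.n_obs):
        eta_i = float(toy_design.X[i, :p] @ th + toy_design.X[i, sl] @ b)
        expected += toy_design.y[i] * eta_i - np.exp(eta_i)
    expected -= float(b @ toy_design.penalty @ b) / (2 * tau2)
    expected -= (th[j] - mu_p) ** 2 / (2 * V_p)
    assert abs(got - expected) < 1e-8 * max(1.0, abs(expected))


def test_adaptive_metropolis_recovers_conjugate_gaussian_posterior():
    """Gaussian likelihood with known variance and a normal prior: the
    sampler must match the closed-form posterior within Monte-Carlo error."""
    rng = np.random.default_rng(42)
    y = rng.normal(1.5, 1.0, size=30)
    n = len(y)
    post_var = 1.0 / (n + 1.0)  # prior N(0, 1), likelihood var 1
    post_mean = y.sum() * post_var

    def lp(x):
        return -0.5 * np.sum((y - x[0]) ** 2) - 0.5 * x[0] ** 2

    draws, accept = adaptive_metropolis(
        lp, np.array([0.0]), n_burn=500, n_keep=4000, seed=7
    )
    chain = draws[:, 0]
    # batch-means standard error accounts for autocorrelation
    batches = chain[: 40 * (len(chain) // 40)].reshape(40, -1).mean(axis=1)
    se = batches.std(ddof=1) / np.sqrt(len(batches))
    assert abs(chain.mean() - post_mean) < 3 * se
    assert chain.std(ddof=1) == pytest.approx(np.sqrt(post_var), rel=0.15)
    assert 0.1 < accept[0] < 0.9


def test_sampler_matches_quadrature_oracle_on_small_glm():
    """Two-parameter Poisson regression: the posterior mean of the slope
    from a long chain agrees with dense 2-D quadrature to 2%."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=200)
    y = rng.poisson(np.exp(1.0 + 0.3 * x)).astype(float)

    def lp(par):
        eta = par[0] + par[1] * x
        return float(y @ eta - np.exp(eta).sum())

    # dense quadrature around the mode
    b0 = np.linspace(0.7, 1.3, 301)
    b1 = np.linspace(0.0, 0.6, 301)
    B0, B1 = np.meshgrid(b0, b1, indexing="ij")
    eta = B0[..., None] + B1[..., None] * x
    loglik = (y * eta - np.exp(eta)).sum(axis=-1)
    w = np.exp(loglik - loglik.max())
    quad_mean = float((w * B1).sum() / w.sum())

    draws, _ = adaptive_metropolis(
        lp, np.array([0.0, 0.0]), n_burn=2000, n_keep=48000, seed=11,
        initial_scales=np.array([0.1, 0.1]),
    )
    assert abs(draws[:, 1].mean() - quad_mean) < 0.02 * abs(quad_mean)


@pytest.fixture(scope="module")
def full_chain(cov1096, sim_halfnoise):
    return sample_posterior(
        cov1096,
        sim_halfnoise.deaths,
        GamSpec(df_per_year=10.0),
        PriorSpec(),
        McmcSettings(seed=99),
    )


def test_flat_prior_posterior_mean_close_to_mle(cov1096, sim_halfnoise, full_chain):
    """Bernstein-von Mises at n ~ 1100: the flat-prior posterior mean of the
    lag-1 coefficient sits within one posterior SD of the penalized MLE."""
    f = freq_gam.fit(cov1096, sim_halfnoise.deaths, GamSpec(df_per_year=10.0))
    d = full_chain.draws("lag1")
    assert abs(d.mean() - f.coef["lag1"]) < d.std(ddof=1)


def test_chain_is_stationary_by_split_rhat(full_chain):
    az = pytest.importorskip("arviz")
    d = full_chain.draws("lag1")
    half = len(d) // 2
    rhat = float(az.rhat(np.stack([d[:half], d[half : 2 * half]])))
    assert rhat < 1.1


def test_acceptance_rates_in_working_range(full_chain):
    assert 0.05 < full_chain.accept_spline < 1.0
    assert np.all(full_chain.accept_param > 0.05)
    assert np.all(full_chain.accept_param < 0.95)


def test_chains_reproducible_given_seed(cov400, truth):
    from pmgam.synthetic_data import linear_predictor, simulate_deaths

    sim = simulate_deaths(
        np.exp(linear_predictor(truth, cov400)), 0.5, truth.sigma_hat, seed=12
    )
    settings = McmcSettings(burn_in=100, iterations=150, seed=5)
    a = sample_posterior(cov400, sim.deaths, GamSpec(df_per_year=4.0), mcmc=settings)
    b = sample_posterior(cov400, sim.deaths, GamSpec(df_per_year=4.0), mcmc=settings)
    np.testing.assert_array_equal(a.param_draws, b.param_draws)
    np.testing.assert_array_equal(a.spline_draws, b.spline_draws)


def test_vague_prior_limit_matches_flat_prior(cov400, truth):
    """A normal prior with enormous variance is indistinguishable from the
    improper flat prior on the same chain seed."""
    from pmgam.synthetic_data import linear_predictor, simulate_deaths

    sim = simulate_deaths(
        np.exp(linear_predictor(truth, cov400)), 0.5, truth.sigma_hat, seed=14
    )
    settings = McmcSettings(burn_in=150, iterations=300, seed=8)
    flat = sample_posterior(cov400, sim.deaths, GamSpec(df_per_year=4.0), PriorSpec(), settings)
    vague = sample_posterior(
        cov400,
        sim.deaths,
        GamSpec(df_per_year=4.0),
        PriorSpec(coef_priors={"lag1": NormalPrior(0.02, 1e6)}),
        settings,
    )
    assert abs(flat.draws("lag1").mean() - vague.draws("lag1").mean()) < 5e-4


def test_inverse_gamma_hyperprior_mode_runs(cov400, truth):
    from pmgam.synthetic_data import linear_predictor, simulate_deaths

    sim = simulate_deaths(
        np.exp(linear_predictor(truth, cov400)), 0.5, truth.sigma_hat, seed=13
    )
    res = sample_posterior(
        cov400,
        sim.deaths,
        GamSpec(df_per_year=4.0),
        PriorSpec(tau2_mode="ig"),
        McmcSettings(burn_in=200, iterations=300, seed=6),
    )
    assert np.all(res.tau2_draws > 0)
    assert res.tau2_draws.std() > 0  # actually sampled, not fixed


def _constant_result(values):
    values = np.asarray(values, dtype=float)[:, None]
    return PosteriorResult(
        param_names=("lag1",),
        param_draws=values,
        spline_draws=np.zeros((len(values), 0)),
        tau2_draws=np.ones(len(values)),
        accept_param=np.array([0.4]),
    )


def test_summary_of_constant_chain():
    s = summarize_posterior(_constant_result([2.5] * 10))
    assert s.loc["lag1", "mean"] == 2.5
    assert s.loc["lag1", "sd"] == 0.0


def test_credible_interval_matches_sort_oracle():
    s = summarize_posterior(_constant_result(np.arange(1.0, 101.0)))
    # 2.5th/97.5th percentiles of 1..100 by the sorted-interpolation rule
    assert s.loc["lag1", "q2.5"] == pytest.approx(1 + 0.025 * 99, abs=1e-12)
    assert s.loc["lag1", "q97.5"] == pytest.approx(1 + 0.975 * 99, abs=1e-12)
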