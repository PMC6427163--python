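"""Fully Bayesian P-spline GAM sampled by MH-within-Gibbs.

Same model as :mod:`pmgam.freq_gam`, but the seasonal-smooth coefficients
carry a random-walk prior with variance ``tau^2`` (the stochastic analogue
of the difference penalty), the parametric coefficients carry flat or
normal priors, and inference uses MCMC on the joint posterior

    p(theta, b, tau^2 | y) ∝ L(y | theta, b) * exp(-b' K b / (2 tau^2))
                              * p(theta) * p(tau^2).

Sampler blocks:

* spline coefficients: a Metropolis-Hastings step with an IWLS-mode
  Gaussian proposal — the working-response Gaussian approximation of the
  full conditional at the current state (Gamerman-style), accepted with the
  exact MH ratio;
* parametric coefficients: componentwise Gaussian random walk, proposal
  scales adapted during burn-in toward ~0.4 acceptance and frozen
  afterwards to preserve detailed balance;
* ``tau^2``: either fixed so the smooth matches a target effective df
  (via the frequentist ``df -> lambda`` calibration, ``tau^2 = 1/lambda``),
  or given an inverse-gamma hyperprior and drawn from its conjugate
  conditional.

The likelihood is the Poisson kernel ``sum(y eta - exp(eta))``, well
defined for the continuous positive responses produced by the lognormal
noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.linalg.lapack import dpotrf, dpotrs

from . import freq_gam
from .design import ModelDesign
from .freq_gam import GamSpec
from .synthetic_data import CovariateSeries


class McmcError(RuntimeError):
    """Sampler failure (acceptance collapse or divergent state)."""


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    var: float

    def __post_init__(self):
        if not self.var > 0:
            raise ValueError("normal prior variance must be positive")


@dataclass(frozen=True)
class PriorSpec:
    """Priors: flat (default) or normal per parametric coefficient; RW smooth.

    ``coef_priors`` maps design-column names (e.g. ``"lag1"``) to normal
    priors; unspecified coefficients get improper flat priors.  ``tau2_mode``
    is ``"fixed-df"`` (default; ``tau^2 = 1/lambda`` at the spec's df
    target), ``"ig"`` (inverse-gamma ``IG(ig_a, ig_b)`` hyperprior), or a
    fixed positive number.
    """

    coef_priors: dict[str, NormalPrior] = field(default_factory=dict)
    tau2_mode: str | float = "fixed-df"
    ig_a: float = 1e-3
    ig_b: float = 1e-3

    def __post_init__(self):
        if isinstance(self.tau2_mode, str):
            if self.tau2_mode not in ("fixed-df", "ig"):
                raise ValueError("tau2_mode must be 'fixed-df', 'ig' or a number")
        elif not self.tau2_mode > 0:
            raise ValueError("fixed tau^2 must be positive")
        if self.ig_a <= 0 or self.ig_b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")


@dataclass(frozen=True)
class McmcSettings:
    burn_in: int = 1000
    iterations: int = 2000  # kept iterations after burn-in
    thinning: int = 1
    seed: int | None = None
    adapt_interval: int = 50
    target_accept: float = 0.4

    def __post_init__(self):
        if self.burn_in <= 0 or self.iterations <= 0 or self.thinning <= 0:
            raise ValueError("burn_in, iterations and thinning must be positive")


@dataclass(frozen=True)
class PosteriorResult:
    """Kept draws and acceptance diagnostics of one chain."""

    param_names: tuple[str, ...]
    param_draws: np.ndarray = field(repr=False)  # n_kept x p
    spline_draws: np.ndarray = field(repr=False)  # n_kept x q
    tau2_draws: np.ndarray = field(repr=False)
    accept_param: np.ndarray = field(repr=False)  # per-coordinate rates
    accept_spline: float = 0.0
    seed: int | None = None
    settings: McmcSettings = McmcSettings()

    @property
    def n_draws(self) -> int:
        return self.param_draws.shape[0]

    def draws(self, name: str) -> np.ndarray:
        return self.param_draws[:, self.param_names.index(name)]


def poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Poisson log-likelihood kernel sum(y*eta - exp(eta))."""
    if not np.all(np.isfinite(eta)) or np.max(eta) > 50:
        raise McmcError("non-finite or overflowing linear predictor")
    return float(y @ eta - np.exp(eta).sum())


def log_posterior(
    theta: np.ndarray,
    b: np.ndarray,
    design: ModelDesign,
    priors: PriorSpec,
    tau2: float,
) -> float:
    """Unnormalized log posterior at a given state (additive constants dropped)."""
    p = design.n_parametric
    eta = design.X[:, :p] @ theta + design.X[:, design.spline_slice] @ b
    lp = poisson_loglik(design.y, eta)
    if b.size and np.isfinite(tau2):
        lp -= float(b @ (design.penalty @ b)) / (2.0 * tau2)
    for name, prior in priors.coef_priors.items():
        j = design.names.index(name)
        lp -= (theta[j] - prior.mean) ** 2 / (2.0 * prior.var)
    if priors.tau2_mode == "ig":
        lp -= (priors.ig_a + 1.0) * math.log(tau2) + priors.ig_b / tau2
    return lp


def _iwls_proposal(Z, y, offset, b, K_over_tau2):
    """Mean and lower Cholesky (of the precision) of the IWLS proposal at b."""
    eta = offset + Z @ b
    mu = np.exp(np.clip(eta, -50, 50))
    z = (eta - offset) + (y - mu) / mu
    P = (Z * mu[:, None]).T @ Z + K_over_tau2
    L, info = dpotrf(P, lower=1, clean=1, overwrite_a=1)
    if info != 0:
        raise McmcError("IWLS proposal precision not positive definite")
    m, info = dpotrs(L, Z.T @ (mu * z), lower=1)
    return m, L


def _gauss_logpdf(x, m, L_lower):
    """log N(x | m, P^{-1}) with P = L L', up to the dimension constant."""
    r = (x - m) @ L_lower  # == L' (x - m)
    return float(np.sum(np.log(np.diag(L_lower)))) - 0.5 * float(r @ r)


def sample_posterior(
    cov: CovariateSeries,
    deaths: np.ndarray,
    spec: GamSpec = GamSpec(),
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcSettings = McmcSettings(),
) -> PosteriorResult:
    """Draw from the posterior of the distributed-lag Bayesian GAM.

    The chain starts at the frequentist penalized fit (posterior mode
    neighbourhood) with proposal scales from its standard errors, which
    makes the short default chain (1000 burn-in + 2000 kept) effective.
    Reproducible given ``mcmc.seed``.
    """
    deaths = np.asarray(deaths, dtype=float)
    start = freq_gam.fit(cov, deaths, dc_replace(spec, quasi_poisson=True))
    design = start.design
    p = design.n_parametric
    sl = design.spline_slice
    Xp = np.ascontiguousarray(design.X[:, :p])
    Z = np.ascontiguousarray(design.X[:, sl])
    y = design.y
    K = design.penalty
    q = Z.shape[1]

    if priors.tau2_mode == "fixed-df":
        tau2 = 1.0 / max(start.lambda_, 1e-10)
        sample_tau2 = False
    elif priors.tau2_mode == "ig":
        tau2 = 1.0 / max(start.lambda_, 1e-10)
        sample_tau2 = True
        eig = np.linalg.eigvalsh(K) if q else np.array([])
        k_rank = int(np.sum(eig > 1e-9 * max(eig.max(), 1.0))) if q else 0
    else:
        tau2 = float(priors.tau2_mode)
        sample_tau2 = False

    rng = np.random.default_rng(mcmc.seed)
    theta = start.beta[:p].copy()
    b = start.beta[sl].copy()
    eta = Xp @ theta + (Z @ b if q else 0.0)
    loglik = poisson_loglik(y, eta)
    ydot = float(y @ eta)  # y'eta, maintained incrementally

    prior_mean = np.full(p, np.nan)
    prior_var = np.full(p, np.inf)
    for name, prior in priors.coef_priors.items():
        if name not in design.names:
            raise ValueError(f"prior given for unknown coefficient {name!r}")
        j = design.names.index(name)
        prior_mean[j] = prior.mean
        prior_var[j] = prior.var

    scales = np.array(
        [2.4 * max(start.se[name], 1e-6) for name in design.names]
    )
    accept_count = np.zeros(p)
    window_count = np.zeros(p)
    spline_accept = 0
    spline_tries = 0

    n_total = mcmc.burn_in + mcmc.iterations
    n_kept = mcmc.iterations // mcmc.thinning
    param_draws = np.empty((n_kept, p))
    spline_draws = np.empty((n_kept, q))
    tau2_draws = np.empty(n_kept)
    kept = 0

    yXp = Xp.T @ y  # per-column y'x, for O(n) likelihood deltas

    for it in range(n_total):
        # --- spline block: IWLS-mode MH ---
        if q:
            Kot = K / tau2
            offset = Xp @ theta
            m1, L1 = _iwls_proposal(Z, y, offset, b, Kot)
            b_star = m1 + solve_triangular(
                L1, rng.standard_normal(q), trans="T", lower=True, check_finite=False
            )
            eta_star = offset + Z @ b_star
            spline_tries += 1
            ok = np.max(eta_star) < 50
            if ok:
                m2, L2 = _iwls_proposal(Z, y, offset, b_star, Kot)
                ydot_star = float(y @ eta_star)
                ll_star = ydot_star - float(np.exp(eta_star).sum())
                log_alpha = (
                    ll_star
                    - float(b_star @ (K @ b_star)) / (2 * tau2)
                    - loglik
                    + float(b @ (K @ b)) / (2 * tau2)
                    + _gauss_logpdf(b, m2, L2)
                    - _gauss_logpdf(b_star, m1, L1)
                )
                if math.log(rng.random()) < log_alpha:
                    b = b_star
                    eta = eta_star
                    loglik = ll_star
                    ydot = ydot_star
                    spline_accept += 1

        # --- tau^2 conditional (hyperprior mode) ---
        if q and sample_tau2:
            quad = float(b @ (K @ b))
            tau2 = 1.0 / rng.gamma(
                priors.ig_a + 0.5 * k_rank, 1.0 / (priors.ig_b + 0.5 * quad)
            )

        # --- parametric block: componentwise adaptive random walk ---
        steps = scales * rng.standard_normal(p)
        logu = np.log(rng.random(p))
        for j in range(p):
            d = steps[j]
            eta_new = eta + d * Xp[:, j]
            mx = eta_new.max()
            if not np.isfinite(mx) or mx > 50:
                continue
            ll_new = ydot + d * yXp[j] - float(np.exp(eta_new).sum())
            delta = ll_new - loglik
            if np.isfinite(prior_var[j]):
                t_new = theta[j] + d
                delta -= ((t_new - prior_mean[j]) ** 2 - (theta[j] - prior_mean[j]) ** 2) / (
                    2.0 * prior_var[j]
                )
            if logu[j] < delta:
                theta[j] += d
                eta = eta_new
                loglik = ll_new
                ydot += d * yXp[j]
                accept_count[j] += 1
                window_count[j] += 1

        # --- adaptation (burn-in only) ---
        if it < mcmc.burn_in and (it + 1) % mcmc.adapt_interval == 0:
            rates = window_count / mcmc.adapt_interval
            scales *= np.exp(rates - mcmc.target_accept)
            np.clip(scales, 1e-8, 1e3, out=scales)
            window_count[:] = 0.0
        if it + 1 == mcmc.burn_in:
            accept_count[:] = 0.0
            if q and spline_tries and spline_accept / spline_tries < 0.01:
                raise McmcError("spline-block acceptance collapsed during burn-in")
            spline_accept = 0
            spline_tries = 0

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            if kept < n_kept:
                param_draws[kept] = theta
                spline_draws[kept] = b
                tau2_draws[kept] = tau2
                kept += 1

    return PosteriorResult(
        param_names=design.names,
        param_draws=param_draws[:kept],
        spline_draws=spline_draws[:kept],
        tau2_draws=tau2_draws[:kept],
        accept_param=accept_count / mcmc.iterations,
        accept_spline=(spline_accept / spline_tries) if spline_tries else 0.0,
        seed=mcmc.seed,
        settings=mcmc,
    )


def summarize_posterior(result: PosteriorResult) -> pd.DataFrame:
    """Posterior mean, SD and central 95% credible interval per coefficient."""
    if result.n_draws == 0:
        raise ValueError("no posterior draws to summarize")
    draws = result.param_draws
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1) if result.n_draws > 1 else 0.0,
            "q2.5": lo,
            "q97.5": hi,
        },
        index=list(result.param_names),
    )


def adaptive_metropolis(
    log_post,
    x0: np.ndarray,
    n_burn: int,
    n_keep: int,
    seed: int | None = None,
    initial_scales: np.ndarray | None = None,
    target_accept: float = 0.4,
    adapt_interval: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic componentwise adaptive random-walk Metropolis sampler.

    Scales adapt during burn-in and are frozen afterwards.  Returns
    ``(draws, acceptance_rates)``.  This is the same parametric-block
    scheme used inside :func:`sample_posterior`, exposed so that low-
    dimensional posteriors can be sampled directly (and cross-checked
    against closed forms or quadrature).
    """
    x = np.array(x0, dtype=float)
    d = x.size
    scales = (
        np.ones(d) if initial_scales is None else np.array(initial_scales, float)
    )
    rng = np.random.default_rng(seed)
    lp = log_post(x)
    draws = np.empty((n_keep, d))
    accept = np.zeros(d)
    window = np.zeros(d)
    for it in range(n_burn + n_keep):
        for j in range(d):
            prop = x.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_new = log_post(prop)
            if math.log(rng.random()) < lp_new - lp:
                x = prop
                lp = lp_new
                window[j] += 1
                if it >= n_burn:
                    accept[j] += 1
        if it < n_burn and (it + 1) % adapt_interval == 0:
            scales *= np.exp(window / adapt_interval - target_accept)
            np.clip(scales, 1e-10, 1e4, out=scales)
            window[:] = 0.0
        if it >= n_burn:
            draws[it - n_burn] = x
    return draws, accept / n_keep
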