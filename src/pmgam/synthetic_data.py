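"""Calibrated generator for daily respiratory-mortality time series.

The generator emulates the Shanghai 2012-2014 setting that motivates the
model comparison: ~32 respiratory deaths/day (SD ~11), a right-skewed,
autocorrelated and seasonal PM2.5 series (mean 55.0, SD 38.6 ug/m3), six
synoptic weather types (SWT), day-of-week effects, and a smooth seasonal
trend.  Simulated deaths are produced by evaluating the true log-linear
model

    log Yhat_t = beta0 + sum_l beta_l * lag_l(t) + S(t) + phi_W[swt_t] + phi[dow_t]

and multiplying the mean series by lognormal noise,

    Y'_t = Yhat_t * exp(eps_t),   eps_t ~ N(0, (gamma * sigma_hat)^2),

where sigma_hat = 0.34 is the SD of log daily deaths in the real series and
gamma scales the amount of unexplained noise.  gamma = 0 reproduces the mean
series exactly; gamma ~ 0.5 reproduces the real-data SD of daily deaths.
PM2.5 coefficients are per 10 ug/m3 (beta_lag units), while the stored
series keeps concentrations in ug/m3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter

DAYS_PER_YEAR = 365.25
MAX_LAG = 7
START_DATE = "2012-01-01"  # a Sunday, so day 1 has day-of-week level 0


class GeneratorError(ValueError):
    """Invalid generator configuration or inputs."""


class ParameterError(GeneratorError):
    """Parameter outside its admissible range."""


@dataclass(frozen=True)
class HarmonicTrend:
    """Smooth seasonal trend: annual sine/cosine plus a semiannual sine.

    ``S(t) = a1 sin(2 pi t / P) + a2 cos(2 pi t / P) + a3 sin(4 pi t / P)``
    with period ``P = 365.25`` days.  Over whole years the variance of ``S``
    is ``(a1^2 + a2^2 + a3^2) / 2``, which :meth:`with_log_variance` uses to
    scale a fixed shape to a target log-scale variance.  A positive ``a2``
    puts the peak near 1 January (winter excess mortality).
    """

    amplitudes: tuple[float, float, float] = (0.0, 0.0, 0.0)
    period: float = DAYS_PER_YEAR

    @classmethod
    def with_log_variance(
        cls,
        variance: float,
        weights: tuple[float, float, float] = (0.3, 1.0, 0.25),
        period: float = DAYS_PER_YEAR,
    ) -> "HarmonicTrend":
        w = np.asarray(weights, dtype=float)
        scale = math.sqrt(2.0 * variance) / math.sqrt(float(w @ w))
        return cls(amplitudes=tuple(scale * w), period=period)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a1, a2, a3 = self.amplitudes
        ang = 2.0 * np.pi * t / self.period
        return a1 * np.sin(ang) + a2 * np.cos(ang) + a3 * np.sin(2.0 * ang)


# Seasonal trend variance chosen so that, together with the exposure, SWT and
# day-of-week terms, the systematic log-scale variance plus gamma^2 * 0.34^2
# noise reaches ~0.34^2 total near gamma = 1 (and the daily-death SD ~11 near
# gamma = 0.5, matching the real series).
DEFAULT_TREND = HarmonicTrend.with_log_variance(0.075)


@dataclass(frozen=True)
class TrueModel:
    """Generative coefficients of the distributed-lag mortality model.

    Defaults are the coefficients estimated on the real Shanghai series:
    log-rate changes per 10 ug/m3 of PM2.5 at lags 1-7, six synoptic weather
    type effects (category 1 is the reference, fixed at 0) and day-of-week
    effects (Sunday, level 0, is the reference).
    """

    beta0: float = 3.9666423
    beta_lag: tuple[float, ...] = (
        0.0049014,
        -0.0020338,
        0.0024222,
        -0.0000745,
        0.0004227,
        0.0006673,
        -0.0004166,
    )
    phi_swt: tuple[float, ...] = (
        0.0,
        -0.0612972,
        -0.0780534,
        -0.0494911,
        -0.0085775,
        -0.0603464,
    )
    phi_dow: tuple[float, ...] = (
        0.0,
        -0.0094768,
        0.0010382,
        -0.0140684,
        -0.0144893,
        -0.0104156,
        -0.0186630,
    )
    seasonal_trend: Callable[[np.ndarray], np.ndarray] = DEFAULT_TREND
    sigma_hat: float = 0.34
    gamma: float = 0.5

    def __post_init__(self):
        if len(self.beta_lag) != MAX_LAG:
            raise ParameterError(f"beta_lag must have length {MAX_LAG}")
        if len(self.phi_swt) != 6:
            raise ParameterError("phi_swt must have length 6")
        if len(self.phi_dow) != 7:
            raise ParameterError("phi_dow must have length 7")
        if self.phi_swt[0] != 0.0 or self.phi_dow[0] != 0.0:
            raise ParameterError("reference levels must be exactly 0")
        if not self.sigma_hat > 0:
            raise ParameterError("sigma_hat must be positive")
        if self.gamma < 0:
            raise ParameterError("gamma must be nonnegative")

    @property
    def sigma(self) -> float:
        """Noise SD on the log scale, sigma = gamma * sigma_hat."""
        return self.gamma * self.sigma_hat


def default_true_model(**overrides) -> TrueModel:
    """The default generative truth (real-data coefficient estimates)."""
    return TrueModel(**overrides)


@dataclass(frozen=True)
class CovariateCalibration:
    """Marginal targets and process settings of the covariate generator.

    PM2.5 is generated as ``exp(seasonal + AR(1) Gaussian)`` and then
    affinely matched to the target marginal mean/SD (analytic lognormal
    moments, averaged over the annual cycle), truncated below at
    ``pm25_min``.  SWT categories are drawn from a season-dependent
    multinomial blending winter-heavy and summer-heavy probability vectors.
    """

    pm25_mean: float = 55.0  # ug/m3
    pm25_sd: float = 38.6  # ug/m3
    pm25_min: float = 3.0  # ug/m3
    ar_coef: float = 0.6
    log_ar_var: float = 0.32
    log_seasonal_amplitude: float = 0.4  # winter-peaking annual cosine
    # SWT levels: 1 hot dry, 2 warm humid, 3 cold dry, 4 moderately dry,
    # 5 moderately humid, 6 cold humid
    swt_winter_probs: tuple[float, ...] = (0.02, 0.05, 0.38, 0.22, 0.08, 0.25)
    swt_summer_probs: tuple[float, ...] = (0.30, 0.35, 0.02, 0.10, 0.20, 0.03)

    def __post_init__(self):
        for probs in (self.swt_winter_probs, self.swt_summer_probs):
            if len(probs) != 6 or abs(sum(probs) - 1.0) > 1e-9:
                raise ParameterError("SWT probabilities must be 6 values summing to 1")
        if not (0 <= self.ar_coef < 1):
            raise ParameterError("ar_coef must lie in [0, 1)")
        if self.pm25_sd <= 0 or self.pm25_mean <= 0:
            raise ParameterError("PM2.5 targets must be positive")


DEFAULT_CALIBRATION = CovariateCalibration()


@dataclass(frozen=True)
class CovariateSeries:
    """Daily covariates: same-day PM2.5 (ug/m3), SWT category and day of week.

    ``pm25_history`` holds the 7 days preceding day 1 so that lags 1-7 are
    defined for the whole series; series loaded from CSV lack it, and fits
    then drop the leading incomplete-lag days.
    """

    pm25: np.ndarray
    swt: np.ndarray
    dow: np.ndarray
    start_date: str = START_DATE
    pm25_history: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.pm25)
        if len(self.swt) != n or len(self.dow) != n:
            raise GeneratorError("covariate columns must have equal length")
        if n < MAX_LAG + 1:
            raise GeneratorError(
                f"series must cover at least {MAX_LAG + 1} days, got {n}"
            )
        if np.any(np.asarray(self.pm25) < 0):
            raise GeneratorError("pm25 must be nonnegative")
        if not np.all(np.isin(self.swt, np.arange(1, 7))):
            raise GeneratorError("swt levels must be in 1..6")
        if not np.all(np.isin(self.dow, np.arange(7))):
            raise GeneratorError("dow levels must be in 0..6")
        if self.pm25_history is not None and len(self.pm25_history) != MAX_LAG:
            raise GeneratorError(f"pm25_history must have length {MAX_LAG}")

    @property
    def n_days(self) -> int:
        return len(self.pm25)

    @property
    def day_index(self) -> np.ndarray:
        return np.arange(1, self.n_days + 1)

    @property
    def dates(self):
        import pandas as pd

        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def lag_matrix(self, lags: Sequence[int] = range(1, MAX_LAG + 1)) -> np.ndarray:
        """PM2.5 at the requested lags, in 10-ug/m3 units (n x len(lags)).

        Entries whose lag reaches before the available history are NaN.
        """
        if self.pm25_history is not None:
            extended = np.concatenate([self.pm25_history, self.pm25])
            offset = MAX_LAG
        else:
            extended = np.asarray(self.pm25, dtype=float)
            offset = 0
        n = self.n_days
        out = np.full((n, len(lags)), np.nan)
        for j, lag in enumerate(lags):
            if lag < 0:
                raise GeneratorError("lags must be nonnegative")
            idx = np.arange(n) + offset - lag
            ok = idx >= 0
            out[ok, j] = extended[idx[ok]]
        return out / 10.0


def _pm25_raw_moments(calib: CovariateCalibration) -> tuple[float, float]:
    """Mean and SD of exp(seasonal + AR) averaged over the annual cycle."""
    grid = np.arange(1461)  # four years of days, covering the cycle evenly
    m = calib.log_seasonal_amplitude * np.cos(2.0 * np.pi * grid / DAYS_PER_YEAR)
    v = calib.log_ar_var
    m1 = float(np.mean(np.exp(m)))
    m2 = float(np.mean(np.exp(2.0 * m)))
    mean = math.exp(v / 2.0) * m1
    second = math.exp(2.0 * v) * m2
    return mean, math.sqrt(second - mean * mean)


def _simulate_pm25(
    n_total: int, calib: CovariateCalibration, rng: np.random.Generator
) -> np.ndarray:
    """PM2.5 in ug/m3 for days 1-MAX_LAG .. n (history first), stationary start."""
    t = np.arange(1 - MAX_LAG, n_total - MAX_LAG + 1, dtype=float)
    seasonal = calib.log_seasonal_amplitude * np.cos(2.0 * np.pi * t / DAYS_PER_YEAR)
    v = calib.log_ar_var
    phi = calib.ar_coef
    innov = rng.normal(0.0, math.sqrt(v * (1.0 - phi * phi)), size=n_total)
    innov[0] = rng.normal(0.0, math.sqrt(v))  # stationary initial state
    ar = lfilter([1.0], [1.0, -phi], innov)
    raw = np.exp(seasonal + ar)
    raw_mean, raw_sd = _pm25_raw_moments(calib)
    a = (calib.pm25_sd / 10.0) / raw_sd
    b = calib.pm25_mean / 10.0 - a * raw_mean
    return np.maximum(10.0 * (a * raw + b), calib.pm25_min)


def _simulate_swt(
    n_days: int, calib: CovariateCalibration, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(1, n_days + 1, dtype=float)
    w_winter = 0.5 * (1.0 + np.cos(2.0 * np.pi * t / DAYS_PER_YEAR))
    probs = w_winter[:, None] * np.asarray(calib.swt_winter_probs) + (
        1.0 - w_winter[:, None]
    ) * np.asarray(calib.swt_summer_probs)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n_days)
    return 1 + (u[:, None] >= cum).sum(axis=1).astype(np.int64)


def generate_covariates(
    n_days: int = 1096,
    seed: int | None = None,
    calibration: CovariateCalibration = DEFAULT_CALIBRATION,
    start_date: str = START_DATE,
) -> CovariateSeries:
    """Draw a covariate realization: PM2.5 (with 7-day history), SWT, DOW.

    The PM2.5 marginal matches the calibration mean/SD (within truncation
    error) for large ``n_days``; the series is autocorrelated with a winter
    peak, SWT frequencies follow the season, and day-of-week cycles 0..6
    starting from the weekday of ``start_date`` day 1.
    """
    if n_days < MAX_LAG + 1:
        raise GeneratorError(
            f"n_days must be at least {MAX_LAG + 1}, got {n_days}"
        )
    rng = np.random.default_rng(seed)
    pm25_all = _simulate_pm25(n_days + MAX_LAG, calibration, rng)
    swt = _simulate_swt(n_days, calibration, rng)
    dow = np.arange(n_days, dtype=np.int64) % 7
    return CovariateSeries(
        pm25=pm25_all[MAX_LAG:],
        swt=swt,
        dow=dow,
        start_date=start_date,
        pm25_history=pm25_all[:MAX_LAG],
    )


def linear_predictor(model: TrueModel, cov: CovariateSeries) -> np.ndarray:
    """Log mean deaths eta_t for every day of the series.

    Days whose lags reach before the available PM2.5 history get NaN (only
    possible for series without a stored history).
    """
    lagmat = cov.lag_matrix(range(1, MAX_LAG + 1))
    t = cov.day_index.astype(float)
    swt = np.asarray(cov.swt)
    dow = np.asarray(cov.dow)
    if np.any(~np.isin(swt, np.arange(1, 7))) or np.any(~np.isin(dow, np.arange(7))):
        raise GeneratorError("unknown SWT or day-of-week category level")
    eta = (
        model.beta0
        + lagmat @ np.asarray(model.beta_lag)
        + np.asarray(model.seasonal_trend(t))
        + np.asarray(model.phi_swt)[swt - 1]
        + np.asarray(model.phi_dow)[dow]
    )
    return eta


def calibrate_intercept(
    model: TrueModel, cov: CovariateSeries, target_mean_deaths: float = 32.0
) -> TrueModel:
    """Offset beta0 so the mean of the mean-death series equals the target.

    The real-data intercept was estimated against covariates we do not
    observe, so it is re-anchored to the observed mean daily deaths (32) on
    each synthetic covariate draw.
    """
    eta = linear_predictor(model, cov)
    mu = np.exp(eta[np.isfinite(eta)])
    if mu.size == 0:
        raise GeneratorError("no days with complete lags to calibrate against")
    shift = math.log(target_mean_deaths) - math.log(float(np.mean(mu)))
    return replace(model, beta0=model.beta0 + shift)


@dataclass(frozen=True)
class SimulatedSeries:
    """Mean series, noisy deaths and the realized noise draws."""

    mean: np.ndarray
    deaths: np.ndarray
    epsilon: np.ndarray
    seed: int | None

    @property
    def n_days(self) -> int:
        return len(self.deaths)


def simulate_deaths(
    mean: np.ndarray,
    gamma: float,
    sigma_hat: float,
    seed: int | None = None,
    round_counts: bool = False,
) -> SimulatedSeries:
    """Multiply the mean series by lognormal noise exp(eps), eps ~ N(0, (gamma sigma_hat)^2).

    ``gamma = 0`` returns the mean series unchanged.  ``round_counts`` rounds
    to the nearest nonnegative integer (off by default: the continuous
    response is fitted by quasi-Poisson scoring, and rounding is negligible
    at mean ~32).
    """
    mean = np.asarray(mean, dtype=float)
    if gamma < 0:
        raise ParameterError("gamma must be nonnegative")
    if sigma_hat <= 0:
        raise ParameterError("sigma_hat must be positive")
    if not np.all(np.isfinite(mean)) or np.any(mean <= 0):
        raise ParameterError("mean series must be finite and positive")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, gamma * sigma_hat, size=mean.shape)
    if gamma == 0:
        eps = np.zeros_like(mean)
        deaths = mean.copy()
    else:
        deaths = mean * np.exp(eps)
    if round_counts:
        deaths = np.maximum(np.rint(deaths), 0.0)
    return SimulatedSeries(mean=mean, deaths=deaths, epsilon=eps, seed=seed)


def simulate_series(
    model: TrueModel,
    cov: CovariateSeries,
    seed: int | None = None,
    round_counts: bool = False,
) -> SimulatedSeries:
    """Convenience wrapper: linear predictor -> mean series -> noisy deaths."""
    eta = linear_predictor(model, cov)
    if np.any(~np.isfinite(eta)):
        raise GeneratorError(
            "series has days with incomplete lags; generate covariates with a history"
        )
    return simulate_deaths(
        np.exp(eta), model.gamma, model.sigma_hat, seed=seed, round_counts=round_counts
    )
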