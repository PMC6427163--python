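# Methods

## The problem

Short-term associations between fine particulate matter (PM2.5) and daily
respiratory mortality are usually estimated from ecological time series with
a semiparametric Poisson regression: daily death counts are regressed on
lagged pollutant concentrations (linear terms) while a smooth function of
calendar time absorbs seasonality and slow confounding trends.  The question
`pmgam` addresses is methodological: does a fully Bayesian generalized
additive model (GAM), with the seasonal smooth represented as a penalized
B-spline (P-spline) under a random-walk prior and sampled by MCMC, recover
the exposure coefficient with the same accuracy and precision as the
conventional frequentist penalized GAM — and how sensitive is it to the
prior?  Because the motivating mortality registry data (Shanghai, 2012–2014)
cannot be redistributed, the package answers this by simulation from a
generator calibrated to the published summary statistics and coefficient
estimates of that setting.

## The model

For day t = 1..n (n = 1096, three years),

    log E(Y_t) = beta0 + sum_{l=1..7} beta_l * x_{t-l} + S(t)
                 + phi_W[swt_t] + phi[dow_t]

where `x_{t-l}` is PM2.5 at lag l in 10-ug/m3 units, `swt_t` is one of six
synoptic weather types (category 1 reference), `dow_t` the day of week
(Sunday reference), and `S(t)` a smooth seasonal trend.  `beta_1`, the lag-1
log-rate change per 10 ug/m3, is the parameter of interest.

`S(t)` is a linear combination of cubic B-splines on equally spaced knots.
Smoothness is imposed through the coefficient differences:

* frequentist: penalty `(lambda/2) * b' K b` with `K = D_r' D_r`, the
  r-th order difference operator (r = 2 by default, r = 1 available);
* Bayesian: the equivalent random-walk prior `b_m = b_{m-1} + u_m` (r = 1)
  or `b_m = 2 b_{m-1} - b_{m-2} + u_m` (r = 2), `u_m ~ N(0, tau^2)`, with
  flat priors on the initial coefficients; `tau^2 = 1/lambda`.

The spline block is reparameterized to a sum-to-zero constraint on its
fitted values (QR null-space construction) so the intercept remains
estimable; after centring, the order-2 penalty leaves exactly one
unpenalized direction (the linear trend), so the smooth's effective degrees
of freedom (edf) range from 1 to the basis dimension minus one.

## Smoothness as a design dial

Following common epidemiological practice, seasonal flexibility is not
selected by GCV/REML but set in "df per year".  Given a target, `lambda` is
found by monotone bisection on `log lambda` so that the trace of the
smooth's influence sub-matrix, `tr[(X'WX + lambda K)^{-1} X'WX]` restricted
to spline columns, equals `df_per_year * years` (tolerance 0.05 edf at the
converged IRLS weights; a fallback bisection over fully converged fits
handles the rare oscillating case).  The knot density adapts to the target
(at least 6 segments per year — the default knot spacing — and
`ceil(df) + 2` per year when more are needed), so one basis serves targets
from 1 to ~20 df/year.  `lambda = 0` gives an unpenalized regression spline.

The Bayesian fit reuses this calibration: by default `tau^2` is fixed at
`1/lambda(df)`, making the two engines match smoothness exactly; an
IG(0.001, 0.001) hyperprior on `tau^2` with its conjugate conditional
update is available as a separate mode.

## Fitting algorithms

**Frequentist.** Penalized IRLS: working response
`z = eta + (y - mu)/mu`, weights `W = diag(mu)`, update
`b = (X'WX + lambda K)^{-1} X'W z`; convergence when the relative change of
the penalized deviance falls below 1e-8 (max 100 iterations).  Standard
errors use the sandwich `V (X'WX) V` with `V = (X'WX + lambda K)^{-1}`,
scaled by the Pearson dispersion `X^2/(n - edf)` in quasi-Poisson mode
(default on: the simulated response is continuous with non-unit dispersion;
point estimates are unaffected).  Days 1–7 are dropped when lags are
incomplete (complete-case); generated series carry a 7-day exposure history
so all days are usable.

**Bayesian.** MH-within-Gibbs, 1000 burn-in + 2000 kept iterations by
default (longer chains change the summaries negligibly at this data size):

* spline block: Gaussian proposal from the IWLS approximation of the full
  conditional at the current state (mean and precision from one weighted
  least-squares step, precision `Z'WZ + K/tau^2`), accepted with the exact
  MH ratio including the reverse-proposal density.  Typical acceptance
  0.85–0.95 at n ~ 1100.
* parametric block: componentwise Gaussian random walk; scales start at
  2.4 x the frequentist SE, adapt every 50 burn-in iterations toward
  acceptance ~0.4 and are frozen afterwards (detailed balance).
* chains start at the penalized-IRLS fit, i.e. near the posterior mode.

Posterior summaries are the mean, SD and 2.5/97.5 percentile interval of
the kept draws.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
with marginals matched to the reported descriptive statistics of the Shanghai series:

* **PM2.5**: `exp(0.4 cos(2 pi t/365.25) + AR1)` with AR coefficient 0.6
  and stationary log-variance 0.32, affinely mapped to mean 55.0 / SD
  38.6 ug/m3 using analytic lognormal moments averaged over the annual
  cycle, truncated below at the observed minimum 3.0 ug/m3.  This yields a
  right-skewed, autocorrelated series with a winter peak; the AR
  coefficient is a modelling choice (configurable), not an estimated one.
* **Seasonal trend**: `S(t) = a1 sin + a2 cos (annual) + a3 sin
  (semiannual)`, weights (0.3, 1.0, 0.25) scaled so Var(S) = 0.075 on the
  log scale.  Together with the exposure, weather-type and day-of-week
  terms this puts the systematic log-variance near 0.08, so that at noise
  level gamma ~ 0.5 the simulated death SD (~10.9) matches the observed
  ~11, and the total log-scale SD approaches the observed 0.34 near
  gamma ~ 1.
* **SWT**: season-dependent multinomial blending a winter-heavy and a
  summer-heavy probability vector with a cosine weight (cold types peak in
  winter).  The marginal frequencies of the real classification are
  unpublished; the chosen vectors are a stand-in.
* **Deaths**: `Y'_t = Yhat_t * exp(eps_t)`, `eps_t ~ N(0, (gamma*0.34)^2)`,
  i.e. multiplicative lognormal noise around the model mean; `gamma = 0` is
  noiseless.  The response stays continuous (no Poisson resampling, no
  rounding by default — an optional flag rounds to integers); fits use the
  quasi-Poisson scoring equations, which are well defined for positive
  continuous responses.
* **Intercept**: after covariates and trend are drawn, `beta0` is offset so
  the mean of the mean-death series is 32/day.  The published intercept was
  estimated against covariates we do not observe, so reusing it raw would
  not reproduce the observed mean level.

What the generator does *not* emulate: true Poisson sampling variation
conditional on the mean (the noise is purely lognormal, matching the
simulation framework under study), exposure measurement error, interactions
between PM2.5 and weather, and the meteorological derivation of the SWT
classes.  Passing recovery tests therefore demonstrate correctness of the
estimators under this generative mechanism, not robustness to those
real-data features.

## Simulation studies

All studies fix the generative coefficients at the real-data coefficient
estimates (beta1 = 0.0049014), share one covariate realization across every
cell (so the exposure–trend concurvity is identical, as it would be with
fixed real covariates), and give replicate r the noise seed
`base_seed + r` (common random numbers across cells; MCMC seeds are offset
from the noise seeds and shared across prior cells so prior effects are not
masked by chain noise).

1. **Engine comparison** over noise gamma in {0.5, ..., 1.0} and df in
   {1..20}/year.  Desk-scale defaults: df in {1, 2, 4, 8, 10, 16}, gamma in
   {0.5, 1.0}, 100 frequentist / 25 Bayesian replicates per cell.
2. **Prior sensitivity** at gamma = 0.5, df = 8/year: normal prior on
   beta1 with mean mu in 0.001..0.020 and variance c*mu, c in
   {0.5, ..., 1.0}; desk scale uses mu in {0.001, 0.005, 0.010, 0.020},
   c in {0.5, 1.0}, 25 replicates, plus flat-prior reference fits on the
   same series.
3. **Truth sensitivity**: true beta1 swept over 0.001..0.020 with the prior
   fixed at N(0.005, 0.0025); cell means are regressed on the truth grid
   (OLS slope, intercept, Pearson R).  Desk scale: four truths, 25
   replicates.

The desk-scale grids resolve the cell means: with per-cell SD
~0.002, 25 replicates give a Monte-Carlo SE of ~0.0004, well inside the
differences of interest; the full-scale grids (20 x 6 x 100 fits) are
reachable through the same API/CLI by widening the grid configuration.

## Numerical choices and edge cases

* edf bisection over log10(lambda) in [-8, 10], 60 steps, tolerance 1e-3.
* IRLS starts at `eta = log(max(y, 0.5))`; linear predictors above 50 on
  the log scale abort the fit (overflow guard); MCMC proposals beyond that
  guard are rejected.
* Single-replicate cells report SD 0; cells with more than 20% failed fits
  are flagged in the summary rather than silently dropped.
* Sample SDs use the n-1 denominator throughout.
* `gamma = 0` returns the mean series bit-exactly (no RNG draw applied).
* Series CSVs store PM2.5 in ug/m3; all coefficients are per 10 ug/m3.

## Known limitations

* The reported real-data coefficient estimates are treated as exact truth; the
  real series itself is unavailable, so the real-data fit is not
  reproduced.
* The original Shanghai analysis does not document its sampler, random-walk
  order or hyperprior; Bayesian results are therefore comparable in
  distribution (Monte-Carlo tolerance), not draw-for-draw.
* The "5.37 excess deaths per day" back-calculation sometimes quoted for
  this setting is not reproduced; no combination of the published coefficient, mean deaths and
  mean exposure yields it unambiguously.
* The constrained distributed-lag form (coefficients as a function of lag)
  and wavelet/time-scale variants are out of scope; lags enter
  unconstrained.
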