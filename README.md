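# pmgam

Frequentist and fully Bayesian P-spline Poisson GAMs for distributed-lag
air-pollution mortality time series, with a calibrated simulation framework
for comparing the two.

## The problem

Time-series studies of fine particulate matter (PM2.5) and daily mortality
estimate the short-term exposure effect with a semiparametric Poisson
regression,

    log E(Y_t) = β₀ + Σ_{l=1..7} β_l·x_{t−l} + S(t) + φ_W·W_t + φ·DOW_t ,

where `Y_t` are daily respiratory deaths, `x_{t−l}` is PM2.5 at lag `l`
(per 10 µg/m³), `W_t` one of six synoptic weather types, `DOW_t` the day of
week, and `S(t)` a smooth seasonal trend that absorbs slowly varying
confounding.  The lag-1 coefficient `β₁` — the log-rate change per
10 µg/m³ of yesterday's PM2.5 — is the quantity of interest.

`pmgam` implements two estimation engines over the same design:

* **frequentist**: penalized IRLS, cubic B-spline `S(t)` with a
  second-order difference penalty, smoothing parameter calibrated so the
  smooth's effective degrees of freedom hit a "df per year" target,
  quasi-Poisson standard errors;
* **Bayesian**: the same P-spline smooth under a random-walk prior
  (variance `τ²` matched to the same df target or given an inverse-gamma
  hyperprior), flat or normal priors on the parametric coefficients, and
  MH-within-Gibbs MCMC (IWLS-mode Gaussian proposals for the spline block,
  adaptive random walk for the parametric block; 1000 burn-in + 2000 kept
  draws by default);

plus a **synthetic-data generator** calibrated to the Shanghai 2012–2014
respiratory-mortality setting (32 deaths/day, SD 11; PM2.5 mean 55.0, SD
38.6 µg/m³; multiplicative lognormal noise `exp(ε)`, `ε ~ N(0, (γ·0.34)²)`)
and **simulation studies** that measure how well each engine recovers `β₁`
across noise levels, seasonal flexibility, priors and true effect sizes.
See `docs/methods.md` for the model, algorithms and calibration details.

## Worked example

```python
import numpy as np
from pmgam import (GamSpec, McmcSettings, calibrate_intercept,
                   default_true_model, generate_covariates, linear_predictor,
                   simulate_deaths, fit, sample_posterior, summarize_posterior)

cov   = generate_covariates(1096, seed=0)            # 3 years of covariates
model = calibrate_intercept(default_true_model(), cov)
sim   = simulate_deaths(np.exp(linear_predictor(model, cov)),
                        gamma=0.5, sigma_hat=0.34, seed=1)

f = fit(cov, sim.deaths, GamSpec(df_per_year=10))
print(f"freq lag1 {f.coef['lag1']:.6f} se {f.se['lag1']:.6f} "
      f"edf {f.edf_smooth:.2f}")

post = sample_posterior(cov, sim.deaths, GamSpec(df_per_year=10),
                        mcmc=McmcSettings(seed=42))
print(summarize_posterior(post).loc[["intercept", "lag1"]].round(6))
```

prints

```
freq lag1 0.005062 se 0.001522 edf 30.01
               mean        sd      q2.5     q97.5
intercept  3.443462  0.021849  3.393473  3.480880
lag1       0.005184  0.001556  0.001927  0.008175
```

The generative truth is `β₁ = 0.0049014`: on this replicate the penalized
MLE is 0.00506 (SE 0.0015) and the flat-prior posterior mean 0.00518
(posterior SD 0.0016) — the two engines agree to well within one standard
error, and both intervals cover the truth.  The smooth used 30 effective df
(10 per year over three years).

The same operations are available from the shell:

```bash
pmgam simulate --n-days 1096 --gamma 0.5 --seed 1 --out series.csv
pmgam fit-freq  --input series.csv --df-per-year 10
pmgam fit-bayes --input series.csv --df-per-year 10 --seed 42
pmgam study1 --config study.yaml --out results/   # also study2, study3
```

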