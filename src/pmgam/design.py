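"""Model-matrix assembly shared by the frequentist and Bayesian fitters.

Builds the full design of the distributed-lag mortality model: an intercept,
PM2.5 lag terms (10-ug/m3 units), synoptic-weather-type and day-of-week
dummies (first level as reference), and a centred B-spline block for the
seasonal trend.  The spline block is reparameterized to satisfy a
sum-to-zero constraint on its fitted values (so the intercept stays
estimable): with ``c = psi' 1`` an orthonormal null-space basis ``Q`` of
``c'`` maps the coefficients to the constrained space, and the difference
penalty transforms as ``K -> Q' K Q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr

from .splines import SplineBasis, build_basis, difference_penalty
from .synthetic_data import CovariateSeries, MAX_LAG


class DesignError(ValueError):
    """Design cannot be assembled from the given series/spec."""


@dataclass(frozen=True)
class ModelDesign:
    """Complete-case design matrix and penalty for one fit."""

    X: np.ndarray = field(repr=False)  # n_valid x p, [parametric | spline]
    y: np.ndarray = field(repr=False)
    names: tuple[str, ...]  # parametric column names
    spline_slice: slice
    penalty: np.ndarray = field(repr=False)  # K in the constrained space
    basis: SplineBasis = field(repr=False)
    constraint: np.ndarray = field(repr=False)  # Q: basis -> constrained coords
    valid_index: np.ndarray = field(repr=False)  # day indices kept (1-based)
    years: float

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def n_parametric(self) -> int:
        return self.spline_slice.start

    def penalty_full(self, lam: float) -> np.ndarray:
        """lam * K padded to the full coefficient dimension."""
        P = np.zeros((self.n_coef, self.n_coef))
        P[self.spline_slice, self.spline_slice] = lam * self.penalty
        return P


def build_design(
    cov: CovariateSeries,
    deaths: np.ndarray,
    lags: tuple[int, ...] = tuple(range(1, MAX_LAG + 1)),
    *,
    segments_per_year: float | None = None,
    degree: int = 3,
    penalty_order: int = 2,
    include_spline: bool = True,
) -> ModelDesign:
    """Assemble the design; rows with incomplete lags are dropped."""
    deaths = np.asarray(deaths, dtype=float)
    if len(deaths) != cov.n_days:
        raise DesignError("deaths and covariates must have equal length")
    lagmat = cov.lag_matrix(lags)
    valid = np.all(np.isfinite(lagmat), axis=1) & np.isfinite(deaths)
    if valid.sum() < len(lags) + 20:
        raise DesignError("too few complete-lag days to fit the model")
    t = cov.day_index.astype(float)

    cols = [np.ones(int(valid.sum()))]
    names = ["intercept"]
    for j, lag in enumerate(lags):
        cols.append(lagmat[valid, j])
        names.append(f"lag{lag}")
    swt = np.asarray(cov.swt)[valid]
    for level in range(2, 7):
        cols.append((swt == level).astype(float))
        names.append(f"swt{level}")
    dow = np.asarray(cov.dow)[valid]
    for level in range(1, 7):
        cols.append((dow == level).astype(float))
        names.append(f"dow{level}")
    P = np.column_stack(cols)

    # spline block on the day index, centred via the sum-to-zero constraint
    basis = build_basis(
        t[valid],
        degree=degree,
        segments_per_year=segments_per_year,
        domain=(float(t.min()), float(t.max())),
    )
    if include_spline:
        psi = basis.psi
        K = difference_penalty(basis.n_basis, penalty_order).matrix
        c = psi.sum(axis=0)[:, None]
        Qfull, _ = qr(c)  # first column spans c; the rest its null space
        Q = Qfull[:, 1:]
        Z = psi @ Q
        Kc = Q.T @ K @ Q
        Kc = 0.5 * (Kc + Kc.T)
        X = np.column_stack([P, Z])
    else:
        Q = np.zeros((basis.n_basis, 0))
        Kc = np.zeros((0, 0))
        X = P

    return ModelDesign(
        X=X,
        y=deaths[valid],
        names=tuple(names),
        spline_slice=slice(P.shape[1], X.shape[1]),
        penalty=Kc,
        basis=basis,
        constraint=Q,
        valid_index=cov.day_index[valid],
        years=(float(t.max()) - float(t.min()) + 1.0) / 365.25,
    )
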