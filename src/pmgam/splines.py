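"""B-spline bases on equally spaced knots and difference penalties.

The seasonal trend ``S(t)`` of the mortality model is represented as a linear
combination of B-spline basis functions defined on an equally spaced knot grid
(a P-spline).  Smoothness is imposed on the basis coefficients either through
a quadratic difference penalty (frequentist fit) or through the equivalent
random-walk prior (Bayesian fit): a first-order walk
``beta_m = beta_{m-1} + u_m`` with Gaussian increments ``u_m ~ N(0, tau^2)``
matches the first-difference penalty, and a second-order walk
``beta_m = 2 beta_{m-1} - beta_{m-2} + u_m`` matches the second-difference
penalty.  Up to the flat directions (the diffuse priors on the initial
coefficients) the walk prior density is ``exp(-beta' K beta / (2 tau^2))``
with ``K = D' D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


class SplineError(ValueError):
    """Invalid basis or penalty construction request."""


class DomainError(SplineError):
    """Evaluation points outside the knot domain."""


@dataclass(frozen=True)
class SplineBasis:
    """Open-uniform B-spline basis of degree ``degree`` on ``n_segments``
    equal segments of ``[x_min, x_max]``.

    The exterior knots continue the interior spacing (``degree`` pad knots on
    each side), so the basis has ``n_segments + degree`` functions, each
    supported on ``degree + 2`` consecutive knots, and sums to one everywhere
    on the interior (partition of unity).
    """

    x_min: float
    x_max: float
    degree: int
    n_segments: int
    knots: np.ndarray = field(repr=False)
    psi: np.ndarray = field(repr=False)  # design matrix at the build points

    @property
    def n_basis(self) -> int:
        return self.n_segments + self.degree

    def design(self, x) -> np.ndarray:
        """Evaluate the basis at new points (dense ``len(x) x n_basis``)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(x < self.x_min - 1e-10) or np.any(x > self.x_max + 1e-10):
            raise DomainError(
                f"points outside spline domain [{self.x_min}, {self.x_max}]"
            )
        x = np.clip(x, self.x_min, self.x_max)
        mat = BSpline.design_matrix(x, self.knots, self.degree)
        return mat.toarray()


def build_basis(
    x,
    n_segments: int | None = None,
    degree: int = 3,
    *,
    segments_per_year: float | None = None,
    domain: tuple[float, float] | None = None,
    days_per_year: float = 365.25,
) -> SplineBasis:
    """Build an equally spaced B-spline basis evaluated at ``x``.

    ``n_segments`` gives the number of interior knot segments directly;
    alternatively ``segments_per_year`` scales the knot density with the span
    of ``x`` measured in days (the convention used for the seasonal trend,
    default 6 segments per year).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if domain is None:
        domain = (float(x.min()), float(x.max()))
    x_min, x_max = float(domain[0]), float(domain[1])
    if not x_max > x_min:
        raise SplineError("spline domain must have positive length")
    if degree < 0:
        raise SplineError("degree must be nonnegative")
    if n_segments is None:
        if segments_per_year is None:
            segments_per_year = 6.0
        years = (x_max - x_min + 1.0) / days_per_year
        n_segments = max(int(round(segments_per_year * years)), degree + 1)
    if n_segments < 1:
        raise SplineError("need at least one knot segment")
    if n_segments + 1 < degree + 1:
        raise SplineError("too few knots for the requested degree")

    h = (x_max - x_min) / n_segments
    knots = x_min + h * np.arange(-degree, n_segments + degree + 1, dtype=float)
    if np.any(x < x_min) or np.any(x > x_max):
        raise DomainError(f"points outside spline domain [{x_min}, {x_max}]")
    psi = BSpline.design_matrix(x, knots, degree).toarray()
    return SplineBasis(
        x_min=x_min,
        x_max=x_max,
        degree=degree,
        n_segments=n_segments,
        knots=knots,
        psi=psi,
    )


@dataclass(frozen=True)
class PenaltyMatrix:
    """Difference penalty ``K = D' D`` of order ``r`` on ``M`` coefficients.

    ``K`` is symmetric positive semidefinite with rank ``M - r``; its null
    space is spanned by polynomial coefficient vectors of degree ``< r``
    (constants for ``r = 1``, constants and linear ramps for ``r = 2``).
    """

    order: int
    matrix: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return self.n_basis - self.order


def difference_penalty(n_basis: int, order: int = 2) -> PenaltyMatrix:
    """Penalty matrix encoding the random-walk prior of the given order."""
    if order not in (1, 2):
        raise SplineError(f"unsupported difference order {order!r}; use 1 or 2")
    if n_basis <= order:
        raise SplineError("penalty needs more coefficients than its order")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return PenaltyMatrix(order=order, matrix=D.T @ D)
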