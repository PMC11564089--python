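"""Natural cubic spline bases and the distributed-lag crossbasis.

A distributed-lag nonlinear model (DLNM) represents the log-odds contribution
of an exposure history ``(T_0, ..., T_L)`` (lag 0 = event day) as

    sum_k  b_var(T_k)^T  Theta  b_lag(k)

where ``b_var`` is a natural cubic spline basis over temperature, ``b_lag``
a natural cubic spline basis over the lag axis, and ``Theta`` the coefficient
matrix.  Each exposure history therefore collapses to a single model row,
the "crossbasis row" ``vec(R^T C)`` with ``R`` the var-basis evaluated at the
lagged temperatures and ``C`` the lag-basis evaluated at lags ``0..L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "ns_basis",
    "log_lag_knots",
    "crossbasis_row",
    "crossbasis_matrix",
]


@dataclass(frozen=True)
class SplineSpec:
    """A natural cubic regression spline: internal knots, boundary knots,
    optional intercept column.

    Basis dimension is ``len(internal_knots) + 1 + intercept``.  The fitted
    spline is piecewise cubic, C2-continuous at the knots, and linear beyond
    the boundary knots.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.internal_knots)
        b0, b1 = (float(b) for b in self.boundary_knots)
        object.__setattr__(self, "internal_knots", ik)
        object.__setattr__(self, "boundary_knots", (b0, b1))
        if not b0 < b1:
            raise ValueError(f"boundary knots must satisfy b0 < b1, got {b0}, {b1}")
        if any(not (b0 < k < b1) for k in ik):
            raise ValueError(f"internal knots {ik} not strictly inside ({b0}, {b1})")
        if any(ik[i] >= ik[i + 1] for i in range(len(ik) - 1)):
            raise ValueError(f"internal knots must be strictly increasing: {ik}")

    @property
    def dim(self) -> int:
        return len(self.internal_knots) + 1 + int(self.intercept)


def _augmented_knots(spec: SplineSpec) -> np.ndarray:
    b0, b1 = spec.boundary_knots
    return np.concatenate([[b0] * 4, spec.internal_knots, [b1] * 4])


def _cubic_design(t: np.ndarray, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Design matrix of the cubic B-spline basis on augmented knots ``t``."""
    n = len(t) - 4
    spl = BSpline(t, np.eye(n), 3, extrapolate=True)
    if deriv:
        spl = spl.derivative(deriv)
    return np.atleast_2d(spl(np.asarray(x, dtype=float)))


def ns_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns a ``(len(x), spec.dim)`` matrix.  Beyond the boundary knots the
    basis is continued linearly (value and first derivative at the boundary),
    so second derivatives vanish identically outside ``boundary_knots``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("ns_basis requires finite x")
    b0, b1 = spec.boundary_knots
    t = _augmented_knots(spec)

    B = _cubic_design(t, np.clip(x, b0, b1))
    lo, hi = x < b0, x > b1
    for mask, b in ((lo, b0), (hi, b1)):
        if mask.any():
            v = _cubic_design(t, [b])
            d = _cubic_design(t, [b], deriv=1)
            B[mask] = v + (x[mask] - b)[:, None] * d

    # natural constraint: zero second derivative at both boundary knots
    C = _cubic_design(t, [b0, b1], deriv=2)
    if not spec.intercept:
        B, C = B[:, 1:], C[:, 1:]
    Z = null_space(C)
    return B @ Z


def log_lag_knots(L: int, n_knots: int) -> tuple[float, ...]:
    """Internal lag knots equally spaced on the log scale over ``(1, L)``.

    For ``L=6, n_knots=3`` this gives approximately (1.565, 2.449, 3.834),
    i.e. ``exp(log(6) * k/4)`` for ``k = 1..3``.
    """
    if L < 1:
        raise ValueError("lag window must have L >= 1 for log-scale knots")
    if n_knots < 0:
        raise ValueError("n_knots must be non-negative")
    if n_knots >= L:
        raise ValueError(f"n_knots={n_knots} must be < L={L}")
    if n_knots == 0:
        return ()
    pts = np.linspace(0.0, np.log(L), n_knots + 2)[1:-1]
    return tuple(np.exp(pts))


@dataclass(frozen=True)
class CrossBasisSpec:
    """Tensor-product (crossbasis) specification for a DLNM.

    ``var_spec`` is the temperature basis; ``lag_spec`` the lag basis over
    ``0..L`` (None collapses the lag dimension to a single constant column,
    the single-lag degenerate case ``L = 0``).
    """

    var_spec: SplineSpec
    lag_spec: SplineSpec | None
    L: int

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("L must be >= 0")
        if self.lag_spec is not None:
            b0, b1 = self.lag_spec.boundary_knots
            if not (b0 <= 0.0 and b1 >= self.L):
                raise ValueError("lag_spec boundary knots must cover [0, L]")

    @property
    def dim_var(self) -> int:
        return self.var_spec.dim

    @property
    def dim_lag(self) -> int:
        return 1 if self.lag_spec is None else self.lag_spec.dim

    @property
    def dim(self) -> int:
        return self.dim_var * self.dim_lag

    def lag_basis_matrix(self) -> np.ndarray:
        """Lag basis evaluated at lags ``0..L`` — shape ``(L+1, dim_lag)``."""
        if self.lag_spec is None:
            return np.ones((self.L + 1, 1))
        return ns_basis(np.arange(self.L + 1, dtype=float), self.lag_spec)

    def lag_weights(self) -> np.ndarray:
        """Column sums of the lag basis: the linear map that cumulates the
        fitted surface over the lag window."""
        return self.lag_basis_matrix().sum(axis=0)


def default_crossbasis(
    var_knots: tuple[float, ...],
    var_boundary: tuple[float, float],
    L: int = 6,
    n_lag_knots: int = 3,
) -> CrossBasisSpec:
    """Crossbasis with var-knots in deg C and log-spaced lag knots on [0, L].

    The lag basis always carries an intercept column so a constant
    distributed-lag effect is representable; short windows reduce the lag
    knot count to ``L - 1`` (0 for ``L <= 1``).
    """
    var_spec = SplineSpec(tuple(var_knots), var_boundary, intercept=False)
    if L == 0:
        return CrossBasisSpec(var_spec, None, 0)
    k = min(n_lag_knots, L - 1)
    lag_spec = SplineSpec(log_lag_knots(L, k), (0.0, float(L)), intercept=True)
    return CrossBasisSpec(var_spec, lag_spec, L)


def crossbasis_matrix(lag_temps: np.ndarray, spec: CrossBasisSpec) -> np.ndarray:
    """Crossbasis rows for ``N`` exposure histories.

    ``lag_temps`` is ``(N, L+1)`` with column ``k`` the temperature at lag
    ``k``.  Row ``i`` is ``vec(R_i^T C)`` (row-major over the var dimension),
    length ``dim_var * dim_lag``.
    """
    lag_temps = np.atleast_2d(np.asarray(lag_temps, dtype=float))
    n, ncol = lag_temps.shape
    if ncol != spec.L + 1:
        raise ValueError(f"expected {spec.L + 1} lag columns, got {ncol}")
    V = ns_basis(lag_temps.ravel(), spec.var_spec).reshape(n, ncol, spec.dim_var)
    C = spec.lag_basis_matrix()
    rows = np.einsum("nlv,lc->nvc", V, C)
    return rows.reshape(n, spec.dim)


def crossbasis_row(lag_vector, spec: CrossBasisSpec) -> np.ndarray:
    """Single crossbasis row for one exposure history (see crossbasis_matrix)."""
    values = np.asarray(getattr(lag_vector, "values", lag_vector), dtype=float)
    if values.ndim != 1 or values.size != spec.L + 1:
        raise ValueError(f"lag vector must have length {spec.L + 1}")
    return crossbasis_matrix(values[None, :], spec)[0]
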