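"""Cumulative exposure-response summaries of a fitted crossbasis.

The fitted coefficient matrix ``Theta`` (var-basis x lag-basis) is collapsed
over the lag dimension with the column sums ``l`` of the lag basis, giving
reduced coefficients ``Theta l`` on the var basis alone.  The cumulative
log-odds contrast between two constant exposure histories then only needs
the var basis, which is how percentile-contrast odds ratios, full curves and
the minimum-mortality temperature (MMT) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .basis import CrossBasisSpec, SplineSpec, ns_basis
from .clogit import FitResult, wald_interval

__all__ = [
    "ReducedCurve",
    "reduce_to_cumulative",
    "cumulative_contrast_vector",
    "or_at",
    "predict_curve",
    "find_mmt",
]


@dataclass
class ReducedCurve:
    """Cumulative exposure-response curve centred at a reference temperature."""

    center: float
    grid: np.ndarray
    log_or: np.ndarray
    se: np.ndarray
    reduced_coefficients: np.ndarray
    reduced_covariance: np.ndarray
    var_spec: SplineSpec

    def odds_ratio(self, level: float = 0.95):
        """(OR, lower, upper) arrays over the grid."""
        z = norm.ppf(0.5 + level / 2.0)
        return (
            np.exp(self.log_or),
            np.exp(self.log_or - z * self.se),
            np.exp(self.log_or + z * self.se),
        )


def reduce_to_cumulative(fit: FitResult, spec: CrossBasisSpec):
    """Collapse a crossbasis fit over the lag dimension.

    Returns ``(reduced_coefficients, reduced_covariance)`` on the var basis:
    ``Theta l`` and ``A Sigma A'`` with ``A = I_var (x) l'``.
    """
    dv, dl = spec.dim_var, spec.dim_lag
    if fit.coefficients.size < spec.dim:
        raise ValueError(
            f"fit has {fit.coefficients.size} coefficients, expected >= {spec.dim}"
        )
    theta = fit.coefficients[: spec.dim].reshape(dv, dl)
    lw = spec.lag_weights()
    A = np.kron(np.eye(dv), lw[None, :])  # (dv, dv*dl)
    reduced = theta @ lw
    cov = A @ fit.covariance[: spec.dim, : spec.dim] @ A.T
    return reduced, (cov + cov.T) / 2.0


def cumulative_contrast_vector(spec: CrossBasisSpec, x: float, x0: float) -> np.ndarray:
    """Full-coefficient contrast for the cumulative log-OR between constant
    histories at ``x`` and ``x0`` — usable directly with wald_interval on the
    crossbasis fit."""
    dvec = (ns_basis([x], spec.var_spec) - ns_basis([x0], spec.var_spec))[0]
    return np.kron(dvec, spec.lag_weights())


def _reduced_fit(reduced_coefficients, reduced_covariance) -> FitResult:
    return FitResult(
        coefficients=np.asarray(reduced_coefficients, dtype=float),
        covariance=np.asarray(reduced_covariance, dtype=float),
        log_likelihood=np.nan,
        n_strata_used=0,
        n_strata_dropped_uninformative=0,
        converged=True,
        iterations=0,
    )


def or_at(
    reduced_coefficients,
    reduced_covariance,
    var_spec: SplineSpec,
    x: float,
    x0: float,
    level: float = 0.95,
):
    """Cumulative OR (and CI) comparing constant exposure at ``x`` versus the
    reference ``x0``, from reduced coefficients."""
    b0, b1 = var_spec.boundary_knots
    if not (b0 <= x <= b1) or not (b0 <= x0 <= b1):
        import warnings

        warnings.warn(
            f"contrast ({x}, {x0}) outside boundary knots ({b0}, {b1}): "
            "linear extrapolation of the spline",
            stacklevel=2,
        )
    contrast = (ns_basis([x], var_spec) - ns_basis([x0], var_spec))[0]
    return wald_interval(_reduced_fit(reduced_coefficients, reduced_covariance), contrast, level)


def predict_curve(
    reduced_coefficients,
    reduced_covariance,
    var_spec: SplineSpec,
    grid,
    center: float,
) -> ReducedCurve:
    """Pointwise cumulative log-OR and s.e. against the reference ``center``
    over ``grid``; the grid point equal to ``center`` is exactly zero."""
    grid = np.asarray(grid, dtype=float)
    rc = np.asarray(reduced_coefficients, dtype=float)
    rcov = np.asarray(reduced_covariance, dtype=float)
    D = ns_basis(grid, var_spec) - ns_basis([center], var_spec)
    log_or = D @ rc
    var = np.einsum("ij,jk,ik->i", D, rcov, D)
    se = np.sqrt(np.maximum(var, 0.0))
    return ReducedCurve(
        center=float(center),
        grid=grid,
        log_or=log_or,
        se=se,
        reduced_coefficients=rc,
        reduced_covariance=rcov,
        var_spec=var_spec,
    )


def find_mmt(curve: ReducedCurve, search_bounds: tuple[float, float] | None = None) -> float:
    """Minimum-mortality temperature: the grid temperature minimizing the
    cumulative log-OR, restricted to ``search_bounds`` (deg C) when given;
    ties resolve to the lowest temperature."""
    mask = np.ones(curve.grid.size, dtype=bool)
    if search_bounds is not None:
        lo, hi = search_bounds
        mask = (curve.grid >= lo) & (curve.grid <= hi)
    if not mask.any():
        raise ValueError("MMT search range contains no grid points")
    sub_grid = curve.grid[mask]
    sub = curve.log_or[mask]
    return float(sub_grid[np.argmin(sub)])  # argmin takes the first (lowest T) tie
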