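"""Two-stage pooling of country-specific results.

Univariate log-OR estimates are pooled with a random-effects model
(DerSimonian-Laird by default, REML optional), with heterogeneity summarized
by Cochran's Q and I^2.  Country-specific cumulative exposure-response
curves are pooled by multivariate meta-regression of their reduced spline
coefficients: y_i ~ N(mu, S_i + Psi) with an unstructured between-country
covariance Psi estimated by REML (method-of-moments fallback).  Because
countries carry their own knot locations in deg C, curves are first
re-expressed on a shared var basis by least-squares projection before
pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2

from .basis import SplineSpec, ns_basis
from .curve import ReducedCurve, predict_curve

__all__ = [
    "MetaResult",
    "pool_univariate",
    "pool_multivariate",
    "pooled_curve",
    "project_curve_coefficients",
]


@dataclass
class MetaResult:
    pooled: np.ndarray
    pooled_covariance: np.ndarray
    tau2: np.ndarray  # scalar (as 0-d/1x1) or PSD matrix
    Q: float
    Q_df: int
    Q_pvalue: float
    I2: float
    weights: np.ndarray
    method: str = "dl"
    converged: bool = True

    def __post_init__(self) -> None:
        expected = 0.0 if self.Q <= 0 else max(0.0, (self.Q - self.Q_df) / self.Q) * 100.0
        if not np.isclose(self.I2, expected, atol=1e-8):
            raise ValueError("I2 inconsistent with Q and its degrees of freedom")


def _q_stat(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    return float(np.sum(w * (y - mu_fe) ** 2)), mu_fe


def _i2(Q: float, df: int) -> float:
    return 0.0 if Q <= 0 else max(0.0, (Q - df) / Q) * 100.0


def _reml_tau2_univariate(y: np.ndarray, v: np.ndarray) -> float:
    def neg2reml(log_tau2: float) -> float:
        t2 = np.exp(log_tau2)
        w = 1.0 / (v + t2)
        mu = np.sum(w * y) / np.sum(w)
        return float(
            np.sum(np.log(v + t2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    res = optimize.minimize_scalar(neg2reml, bounds=(-30.0, 10.0), method="bounded")
    t2 = float(np.exp(res.x))
    return 0.0 if t2 < 1e-10 else t2


def pool_univariate(estimates, variances, method: str = "dl") -> MetaResult:
    """Random-effects pooling of scalar estimates (log-ORs).

    DerSimonian-Laird: tau^2 = max(0, (Q - df) / (S1 - S2/S1)) with
    S_r = sum of w^r, w = 1/variance; pooled estimate is inverse-variance
    weighted with weights 1/(variance + tau^2).
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.ndim != 1 or y.shape != v.shape:
        raise ValueError("estimates and variances must be matching 1-d arrays")
    if np.any(v <= 0):
        raise ValueError("variances must be strictly positive")
    n = y.size
    if n == 1:
        warnings.warn("single estimate: returned unpooled", stacklevel=2)
        return MetaResult(
            pooled=y.copy(),
            pooled_covariance=np.array([[v[0]]]),
            tau2=np.array(0.0),
            Q=0.0,
            Q_df=0,
            Q_pvalue=1.0,
            I2=0.0,
            weights=np.array([1.0]),
            method=method,
        )
    Q, _ = _q_stat(y, v)
    df = n - 1
    if method == "dl":
        w = 1.0 / v
        s1, s2 = w.sum(), (w**2).sum()
        tau2 = max(0.0, (Q - df) / (s1 - s2 / s1))
    elif method == "reml":
        tau2 = _reml_tau2_univariate(y, v)
    elif method == "fixed":
        tau2 = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    wr = 1.0 / (v + tau2)
    pooled = float(np.sum(wr * y) / np.sum(wr))
    pooled_var = 1.0 / np.sum(wr)
    return MetaResult(
        pooled=np.array([pooled]),
        pooled_covariance=np.array([[pooled_var]]),
        tau2=np.array(tau2),
        Q=Q,
        Q_df=df,
        Q_pvalue=float(chi2.sf(Q, df)),
        I2=_i2(Q, df),
        weights=wr / wr.sum(),
        method=method,
    )


def _psd_project(M: np.ndarray) -> np.ndarray:
    M = (M + M.T) / 2.0
    vals, vecs = np.linalg.eigh(M)
    return (vecs * np.maximum(vals, 0.0)) @ vecs.T


def _mv_mom_psi(ys: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Moment estimate of the between-study covariance: PSD part of the
    sample covariance of the estimates minus the mean within-study
    covariance."""
    if ys.shape[0] < 2:
        return np.zeros((ys.shape[1],) * 2)
    samp = np.cov(ys, rowvar=False, ddof=1)
    return _psd_project(np.atleast_2d(samp) - covs.mean(axis=0))


def _mv_gls(ys: np.ndarray, vs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GLS mean and covariance for per-study covariances ``vs``."""
    p = ys.shape[1]
    wsum = np.zeros((p, p))
    wy = np.zeros(p)
    for y_i, V in zip(ys, vs):
        Wi = linalg.inv(V)
        wsum += Wi
        wy += Wi @ y_i
    cov = linalg.inv(wsum)
    return cov @ wy, (cov + cov.T) / 2.0


def _mv_neg2reml(ys: np.ndarray, covs: np.ndarray, Lflat: np.ndarray) -> float:
    p = ys.shape[1]
    L = np.zeros((p, p))
    L[np.tril_indices(p)] = Lflat
    psi = L @ L.T
    vs = covs + psi[None, :, :]
    try:
        mu, _ = _mv_gls(ys, vs)
    except linalg.LinAlgError:
        return 1e12
    total = 0.0
    wsum = np.zeros((p, p))
    for y_i, V in zip(ys, vs):
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e12
        Wi = linalg.inv(V)
        wsum += Wi
        r = y_i - mu
        total += logdet + float(r @ Wi @ r)
    sign, logdet_w = np.linalg.slogdet(wsum)
    return total + logdet_w


def pool_multivariate(coefficient_vectors, covariances, method: str = "reml") -> MetaResult:
    """Random-effects multivariate meta-analysis of coefficient vectors.

    All vectors must live on a shared basis (same knots); see
    :func:`project_curve_coefficients`.  ``method``: "reml" (default, with
    method-of-moments fallback on non-convergence), "mm", or "fixed"
    (Psi = 0, the GLS combination).
    """
    ys = np.atleast_2d(np.asarray(coefficient_vectors, dtype=float))
    covs = np.asarray(covariances, dtype=float)
    n, p = ys.shape
    if covs.shape != (n, p, p):
        raise ValueError(f"covariances must have shape {(n, p, p)}")
    for V in covs:
        if np.linalg.eigvalsh((V + V.T) / 2).min() < -1e-8 * max(1.0, np.abs(V).max()):
            raise ValueError("within-study covariance is not PSD")
    if p == 1:
        # scalar case: delegate to the univariate pooling machinery
        uni = pool_univariate(
            ys[:, 0], covs[:, 0, 0], method={"mm": "dl", "reml": "reml", "fixed": "fixed"}[method]
        )
        uni.tau2 = np.atleast_2d(uni.tau2)
        return uni

    # heterogeneity against the fixed-effects GLS fit
    mu_fe, _ = _mv_gls(ys, covs)
    Q = 0.0
    for y_i, V in zip(ys, covs):
        r = y_i - mu_fe
        Q += float(r @ linalg.inv(V) @ r)
    df = (n - 1) * p

    converged = True
    if method == "fixed":
        psi = np.zeros((p, p))
        used = "fixed"
    else:
        psi = _mv_mom_psi(ys, covs)
        used = "mm"
        if method == "reml":
            L0 = np.linalg.cholesky(psi + 1e-8 * np.eye(p))
            x0 = L0[np.tril_indices(p)]
            res = optimize.minimize(
                lambda x: _mv_neg2reml(ys, covs, x),
                x0,
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if res.success or res.fun < _mv_neg2reml(ys, covs, x0):
                L = np.zeros((p, p))
                L[np.tril_indices(p)] = res.x
                psi = L @ L.T
                used = "reml"
                converged = bool(res.success)
            else:
                warnings.warn("multivariate REML failed; using moment estimate", stacklevel=2)
                converged = False

    vs = covs + psi[None, :, :]
    mu, cov = _mv_gls(ys, vs)
    # per-study weight summary: trace of the normalized GLS weight matrices
    traces = np.array([np.trace(linalg.inv(V)) for V in vs])
    return MetaResult(
        pooled=mu,
        pooled_covariance=cov,
        tau2=_psd_project(psi),
        Q=Q,
        Q_df=df,
        Q_pvalue=float(chi2.sf(Q, df)),
        I2=_i2(Q, df),
        weights=traces / traces.sum(),
        method=used,
        converged=converged,
    )


def project_curve_coefficients(
    reduced_coefficients,
    reduced_covariance,
    from_spec: SplineSpec,
    to_spec: SplineSpec,
    grid,
    from_center: float,
    to_center: float,
    grid_offset: float = 0.0,
):
    """Re-express a reduced curve on a shared var basis by least squares.

    The source curve (centred at ``from_center``) is evaluated through its
    centred basis on ``grid + grid_offset`` (absolute deg C for the source);
    the target basis is evaluated at ``grid`` centred at ``to_center``.  The
    resulting linear map is applied to both coefficients and covariance, so
    the projection is exact for any coefficient value.
    """
    grid = np.asarray(grid, dtype=float)
    Bf = ns_basis(grid + grid_offset, from_spec) - ns_basis([from_center + grid_offset], from_spec)
    Bt = ns_basis(grid, to_spec) - ns_basis([to_center], to_spec)
    M, *_ = np.linalg.lstsq(Bt, Bf, rcond=None)
    rc = M @ np.asarray(reduced_coefficients, dtype=float)
    rcov = M @ np.asarray(reduced_covariance, dtype=float) @ M.T
    return rc, (rcov + rcov.T) / 2.0


def pooled_curve(
    meta: MetaResult, var_spec: SplineSpec, grid, center: float
) -> ReducedCurve:
    """Cumulative curve from pooled coefficients (delegates to predict_curve)."""
    if meta.pooled.size != var_spec.dim:
        raise ValueError(
            f"pooled vector of length {meta.pooled.size} does not match basis dim {var_spec.dim}"
        )
    return predict_curve(meta.pooled, meta.pooled_covariance, var_spec, grid, center)


def forest_table(rows: list[dict], meta: MetaResult, outcome: str) -> pd.DataFrame:
    """Country rows plus a pooled row with heterogeneity statistics."""
    recs = list(rows)
    z = 1.959963984540054
    mu = float(meta.pooled[0])
    se = float(np.sqrt(meta.pooled_covariance[0, 0]))
    recs.append(
        {
            "country": "POOLED",
            "outcome": outcome,
            "or": float(np.exp(mu)),
            "ci_low": float(np.exp(mu - z * se)),
            "ci_high": float(np.exp(mu + z * se)),
            "weight_percent": 100.0,
            "Q": meta.Q,
            "Q_pvalue": meta.Q_pvalue,
            "I2": meta.I2,
        }
    )
    return pd.DataFrame(recs)
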