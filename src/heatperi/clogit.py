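"""Conditional logistic regression for 1:M matched case-crossover strata.

With exactly one case per stratum the conditional likelihood is the softmax
likelihood

    l(beta) = sum_strata [ x_case . beta - log sum_j exp(x_j . beta) ]

which is concave; it is maximized by Newton-Raphson with the analytic
gradient and Hessian, step-halving on any likelihood decrease.  Stratum-level
intercepts are conditioned out, so any column that is constant within every
stratum carries no information — such columns (and exactly collinear ones)
are detected after within-stratum centering and dropped, with the returned
coefficient vector re-expanded to the full design dimension (zeros in the
dropped positions) so downstream crossbasis layouts are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import norm

__all__ = ["FitResult", "fit_conditional_logistic", "wald_interval", "ZeroInformationError"]


class ZeroInformationError(ValueError):
    """No stratum shows within-stratum variation in the design."""


@dataclass
class FitResult:
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_strata_used: int
    n_strata_dropped_uninformative: int
    converged: bool
    iterations: int
    dropped_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.converged and not np.all(np.isfinite(self.coefficients)):
            raise ValueError("converged fit must have finite coefficients")


def _group_starts(groups: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])


def _loglik_parts(X, y, beta, starts, case_rows):
    eta = X @ beta
    gmax = np.maximum.reduceat(eta, starts)
    ex = np.exp(eta - np.repeat(gmax, np.diff(np.r_[starts, len(eta)])))
    denom = np.add.reduceat(ex, starts)
    ll = float(eta[case_rows].sum() - (np.log(denom) + gmax).sum())
    p = ex / np.repeat(denom, np.diff(np.r_[starts, len(eta)]))
    return ll, p


def fit_conditional_logistic(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    extra_columns: np.ndarray | None = None,
    max_iter: int = 100,
    tol_loglik: float = 1e-10,
    tol_score: float = 1e-8,
) -> FitResult:
    """Fit the stratified conditional logistic model.

    Parameters
    ----------
    X : (N, k) design matrix (e.g. crossbasis rows), one row per person-day.
    y : (N,) case indicator — exactly one True per stratum.
    groups : (N,) stratum labels.
    extra_columns : optional (N, m) adjustment columns appended to X (e.g. a
        relative-humidity crossbasis).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if extra_columns is not None:
        X = np.hstack([X, np.atleast_2d(np.asarray(extra_columns, dtype=float))])
    y = np.asarray(y, dtype=bool)
    groups = np.asarray(groups)
    n, k = X.shape

    order = np.argsort(groups, kind="stable")
    X, y, groups = X[order], y[order], groups[order]
    starts = _group_starts(groups)
    sizes = np.diff(np.r_[starts, n])
    cases_per = np.add.reduceat(y.astype(int), starts)
    if np.any(cases_per != 1):
        raise ValueError("each stratum must contain exactly one case row")

    # within-stratum centering: conditioning absorbs stratum effects, so only
    # deviations from the stratum mean are identified
    gmean = np.add.reduceat(X, starts, axis=0) / sizes[:, None]
    Xc = X - np.repeat(gmean, sizes, axis=0)

    scale = np.abs(Xc).max(axis=0) if k else np.zeros(0)
    nz_cols = scale > 1e-12
    if not nz_cols.any():
        raise ZeroInformationError(
            "no stratum with within-stratum design variation; nothing to fit"
        )
    informative_rows = np.abs(Xc[:, nz_cols]).max(axis=1) > 1e-12
    strat_info = np.add.reduceat(informative_rows.astype(int), starts) > 0
    n_dropped_strata = int((~strat_info).sum())
    keep_rows = np.repeat(strat_info, sizes)
    if not strat_info.any():
        raise ZeroInformationError(
            "no stratum with within-stratum design variation; nothing to fit"
        )
    Xc, y2, groups2 = Xc[keep_rows], y[keep_rows], groups[keep_rows]
    starts2 = _group_starts(groups2)

    # drop aliased columns (constant-within-stratum or exactly collinear)
    col_norm = np.linalg.norm(Xc, axis=0)
    nonzero = col_norm > 1e-10 * max(1.0, col_norm.max() if k else 1.0)
    kept = np.flatnonzero(nonzero)
    if kept.size:
        _, R, piv = linalg.qr(Xc[:, kept], mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int((diag > 1e-9 * max(diag.max(), 1.0)).sum())
        kept = np.sort(kept[piv[:rank]])
    dropped_cols = tuple(int(c) for c in np.setdiff1d(np.arange(k), kept))
    if kept.size == 0:
        raise ZeroInformationError("all design columns are aliased within strata")
    Xf = Xc[:, kept]
    case_rows = np.flatnonzero(y2)

    beta = np.zeros(kept.size)
    ll, p = _loglik_parts(Xf, y2, beta, starts2, case_rows)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y2.astype(float) - p
        score = Xf.T @ resid
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        M = np.add.reduceat(p[:, None] * Xf, starts2, axis=0)
        H = Xf.T @ (p[:, None] * Xf) - M.T @ M  # observed information
        try:
            step = linalg.solve(H, score, assume_a="pos")
        except linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving: the likelihood is concave, but guard long steps
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            new_ll, new_p = _loglik_parts(Xf, y2, cand, starts2, case_rows)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        if not np.isfinite(new_ll):
            break
        rel_change = abs(new_ll - ll) / max(1.0, abs(ll))
        beta, ll, p = cand, new_ll, new_p
        if rel_change < tol_loglik:
            converged = True
            break

    M = np.add.reduceat(p[:, None] * Xf, starts2, axis=0)
    H = Xf.T @ (p[:, None] * Xf) - M.T @ M
    try:
        cov_kept = linalg.inv(H)
    except linalg.LinAlgError:
        cov_kept = np.linalg.pinv(H)
    cov_kept = (cov_kept + cov_kept.T) / 2.0

    if np.any(np.abs(beta) > 20):
        warnings.warn(
            "coefficient magnitude > 20: possible separation in the matched data",
            stacklevel=2,
        )
    if not converged:
        warnings.warn(f"conditional logistic fit did not converge in {max_iter} iterations",
                      stacklevel=2)

    full_beta = np.zeros(k)
    full_beta[kept] = beta
    full_cov = np.zeros((k, k))
    full_cov[np.ix_(kept, kept)] = cov_kept
    return FitResult(
        coefficients=full_beta,
        covariance=full_cov,
        log_likelihood=ll,
        n_strata_used=int(strat_info.sum()),
        n_strata_dropped_uninformative=n_dropped_strata,
        converged=converged,
        iterations=it,
        dropped_columns=dropped_cols,
    )


def wald_interval(fit: FitResult, contrast: np.ndarray, level: float = 0.95):
    """Odds ratio and Wald CI for a linear contrast of the coefficients:
    ``exp(c'b +/- z * sqrt(c' Sigma c))``."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != fit.coefficients.shape:
        raise ValueError("contrast length must match coefficient vector")
    eigmin = np.linalg.eigvalsh(fit.covariance).min()
    if eigmin < -1e-8 * max(1.0, np.abs(fit.covariance).max()):
        raise ValueError("covariance matrix is not positive semi-definite")
    est = float(c @ fit.coefficients)
    var = float(c @ fit.covariance @ c)
    se = np.sqrt(max(var, 0.0))
    z = norm.ppf(0.5 + level / 2.0)
    return float(np.exp(est)), float(np.exp(est - z * se)), float(np.exp(est + z * se))
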