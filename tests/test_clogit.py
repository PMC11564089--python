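"""Conditional logistic regression: closed forms, brute-force likelihood
oracles, and an independent library cross-check."""

import numpy as np
import pytest

from heatperi.clogit import (
    ZeroInformationError,
    FitResult,
    fit_conditional_logistic,
    wald_interval,
)


def conditional_loglik(X, y, groups, beta):
    """Direct evaluation of the stratified conditional log-likelihood."""
    ll = 0.0
    for g in np.unique(groups):
        m = groups == g
        eta = X[m] @ beta
        ll += eta[y[m]][0] - np.logaddexp.reduce(eta)
    return ll


def matched_pairs_data(n10=8, n01=2):
    """1:1 pairs with a single binary exposure; n10 pairs have the case
    exposed and control unexposed, n01 the reverse."""
    X, y, g = [], [], []
    for i in range(n10 + n01):
        exposed_case = i < n10
        X += [[1.0 if exposed_case else 0.0], [0.0 if exposed_case else 1.0]]
        y += [True, False]
        g += [i, i]
    return np.array(X), np.array(y), np.array(g)


class TestClosedForms:
    def test_matched_pairs(self):
        X, y, g = matched_pairs_data(8, 2)
        fit = fit_conditional_logistic(X, y, g)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(8 / 2), abs=1e-6)
        assert np.sqrt(fit.covariance[0, 0]) == pytest.approx(np.sqrt(1 / 8 + 1 / 2), abs=1e-6)

    def test_score_zero_at_optimum(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        g = np.repeat(np.arange(10), 4)
        y = np.zeros(40, dtype=bool)
        y[::4] = True
        fit = fit_conditional_logistic(X, y, g)
        eps = 1e-6
        for j in range(3):
            b = fit.coefficients.copy()
            b[j] += eps
            up = conditional_loglik(X, y, g, b)
            b[j] -= 2 * eps
            dn = conditional_loglik(X, y, g, b)
            assert abs((up - dn) / (2 * eps)) < 1e-5


class TestGridOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_two_covariate_three_strata(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 2))
        g = np.repeat(np.arange(3), 4)
        y = np.zeros(12, dtype=bool)
        y[[0, 4, 8]] = True
        fit = fit_conditional_logistic(X, y, g)
        # coarse-to-fine dense grid maximization of the same likelihood
        center, width = np.zeros(2), 4.0
        for _ in range(6):
            b1 = np.linspace(center[0] - width, center[0] + width, 41)
            b2 = np.linspace(center[1] - width, center[1] + width, 41)
            vals = np.array(
                [[conditional_loglik(X, y, g, np.array([a, b])) for b in b2] for a in b1]
            )
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            center = np.array([b1[i], b2[j]])
            width = width * (2 / 40) * 2
        assert np.max(np.abs(fit.coefficients - center)) < 1e-4

    def test_single_covariate_grid(self):
        X = np.array([[0.0], [1.0], [2.0], [0.5], [1.5], [0.0]])
        g = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([True, False, False, True, False, False])
        fit = fit_conditional_logistic(X, y, g)
        grid = np.linspace(-6, 2, 80001)
        lls = [conditional_loglik(X, y, g, np.array([b])) for b in grid]
        assert abs(fit.coefficients[0] - grid[int(np.argmax(lls))]) < 1e-4


class TestInvariances:
    def test_constant_within_stratum_column_dropped(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 2))
        g = np.repeat(np.arange(5), 4)
        y = np.zeros(20, dtype=bool)
        y[::4] = True
        base = fit_conditional_logistic(X, y, g)
        # append a column constant within every stratum (stratum id itself)
        X2 = np.column_stack([X, g.astype(float) * 3.0 + 1.0])
        aug = fit_conditional_logistic(X2, y, g)
        assert 2 in aug.dropped_columns
        np.testing.assert_allclose(aug.coefficients[:2], base.coefficients, atol=1e-10)
        assert aug.log_likelihood == pytest.approx(base.log_likelihood, abs=1e-10)

    def test_zero_information_raises(self):
        X = np.ones((8, 2))
        g = np.repeat(np.arange(2), 4)
        y = np.zeros(8, dtype=bool)
        y[::4] = True
        with pytest.raises(ZeroInformationError):
            fit_conditional_logistic(X, y, g)

    def test_uninformative_strata_counted(self):
        X = np.array([[0.0], [1.0], [5.0], [5.0], [0.9], [0.3]])
        g = np.array([0, 0, 1, 1, 2, 2])
        y = np.array([True, False, True, False, True, False])
        fit = fit_conditional_logistic(X, y, g)
        assert fit.n_strata_used == 2
        assert fit.n_strata_dropped_uninformative == 1

    def test_two_cases_in_stratum_rejected(self):
        X = np.arange(4.0)[:, None]
        g = np.array([0, 0, 0, 0])
        y = np.array([True, True, False, False])
        with pytest.raises(ValueError):
            fit_conditional_logistic(X, y, g)

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(11)
        n_strata = 60
        X = rng.normal(size=(n_strata * 5, 3))
        g = np.repeat(np.arange(n_strata), 5)
        beta_true = np.array([0.5, -0.3, 0.0])
        y = np.zeros(n_strata * 5, dtype=bool)
        for s in range(n_strata):
            rows = slice(s * 5, s * 5 + 5)
            p = np.exp(X[rows] @ beta_true)
            y[s * 5 + rng.choice(5, p=p / p.sum())] = True
        ours = fit_conditional_logistic(X, y, g)
        ref = ConditionalLogit(y.astype(int), X, groups=g).fit(disp=0)
        # agreement limited by statsmodels' own optimizer tolerance
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-4)
        np.testing.assert_allclose(np.sqrt(np.diag(ours.covariance)), ref.bse, atol=1e-4)


class TestWaldInterval:
    def _fit(self, beta, var):
        return FitResult(
            coefficients=np.atleast_1d(np.asarray(beta, float)),
            covariance=np.atleast_2d(np.asarray(var, float)),
            log_likelihood=0.0,
            n_strata_used=1,
            n_strata_dropped_uninformative=0,
            converged=True,
            iterations=1,
        )

    def test_null_contrast(self):
        fit = self._fit([0.7], [[0.2]])
        assert wald_interval(fit, [0.0]) == (1.0, 1.0, 1.0)

    def test_headline_interval_shape(self):
        fit = self._fit([0.2927], [[0.145**2]])
        orr, lo, hi = wald_interval(fit, [1.0])
        assert orr == pytest.approx(1.34, abs=0.005)
        assert lo == pytest.approx(1.01, abs=0.005)
        assert hi == pytest.approx(1.78, abs=0.005)

    def test_interval_brackets_and_widens(self):
        fit = self._fit([0.3], [[0.04]])
        prev_width = 0.0
        for level in (0.5, 0.8, 0.95, 0.99):
            orr, lo, hi = wald_interval(fit, [1.0], level=level)
            assert lo < orr < hi
            width = np.log(hi) - np.log(lo)
            assert width > prev_width
            prev_width = width

    def test_non_psd_covariance_rejected(self):
        fit = self._fit([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            wald_interval(fit, [1.0, 0.0])
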