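"""Random-effects pooling: DerSimonian-Laird hand checks, GLS oracles for
the multivariate model, and curve pooling."""

import numpy as np
import pytest
from scipy import linalg

from heatperi.basis import SplineSpec, ns_basis
from heatperi.curve import predict_curve
from heatperi.meta import (
    pool_multivariate,
    pool_univariate,
    pooled_curve,
    project_curve_coefficients,
)


class TestUnivariate:
    def test_dersimonian_laird_hand_fixture(self):
        """estimates (0, 0.4), both se 0.1: w=100 each, Q=8, df=1,
        tau2 = 7/100 = 0.07, I2 = 87.5%."""
        m = pool_univariate([0.0, 0.4], [0.01, 0.01], method="dl")
        assert m.Q == pytest.approx(8.0, abs=1e-12)
        assert m.Q_df == 1
        assert float(m.tau2) == pytest.approx(0.07, abs=1e-12)
        assert m.I2 == pytest.approx(87.5, abs=1e-10)

    def test_homogeneous_inputs(self):
        m = pool_univariate([0.2, 0.2], [0.01, 0.04], method="dl")
        assert float(m.pooled[0]) == pytest.approx(0.2)
        assert m.Q == pytest.approx(0.0, abs=1e-12)
        assert float(m.tau2) == 0.0
        assert m.I2 == 0.0

    def test_pooled_within_input_range(self, rng):
        for _ in range(20):
            n = rng.integers(2, 8)
            y = rng.normal(size=n)
            v = rng.uniform(0.01, 0.5, size=n)
            for method in ("dl", "reml", "fixed"):
                m = pool_univariate(y, v, method=method)
                assert y.min() - 1e-12 <= m.pooled[0] <= y.max() + 1e-12
                assert m.weights.sum() == pytest.approx(1.0)
                # heterogeneity identity on every result
                expected = 0.0 if m.Q <= 0 else max(0.0, (m.Q - m.Q_df) / m.Q) * 100
                assert m.I2 == pytest.approx(expected)

    def test_duplication_fixed_effects_halves_variance(self):
        y, v = np.array([0.1, 0.3, 0.5]), np.array([0.02, 0.05, 0.04])
        a = pool_univariate(y, v, method="fixed")
        b = pool_univariate(np.r_[y, y], np.r_[v, v], method="fixed")
        assert b.pooled[0] == pytest.approx(a.pooled[0])
        assert b.pooled_covariance[0, 0] == pytest.approx(a.pooled_covariance[0, 0] / 2)

    def test_single_study_returned_unpooled(self):
        with pytest.warns(UserWarning):
            m = pool_univariate([0.3], [0.01])
        assert m.pooled[0] == 0.3
        assert m.Q_df == 0

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError):
            pool_univariate([0.1, 0.2], [0.01, 0.0])


class TestMultivariate:
    def _random_inputs(self, rng, n=4, p=3):
        ys = rng.normal(size=(n, p))
        covs = []
        for _ in range(n):
            A = rng.normal(size=(p, p))
            covs.append(A @ A.T / p + 0.05 * np.eye(p))
        return ys, np.array(covs)

    def test_identical_vectors_give_zero_psi(self, rng):
        y = rng.normal(size=4)
        ys = np.tile(y, (3, 1))
        covs = np.array([np.eye(4) * 0.1] * 3)
        m = pool_multivariate(ys, covs, method="reml")
        np.testing.assert_allclose(m.pooled, y, atol=1e-6)
        assert np.abs(m.tau2).max() < 1e-4

    def test_fixed_effects_matches_gls_oracle(self, rng):
        ys, covs = self._random_inputs(rng)
        m = pool_multivariate(ys, covs, method="fixed")
        W = [linalg.inv(V) for V in covs]
        Wsum = linalg.inv(sum(W))
        mu = Wsum @ sum(Wi @ y for Wi, y in zip(W, ys))
        np.testing.assert_allclose(m.pooled, mu, atol=1e-10)
        np.testing.assert_allclose(m.pooled_covariance, (Wsum + Wsum.T) / 2, atol=1e-10)

    def test_dimension_one_matches_univariate(self, rng):
        y = rng.normal(size=5)
        v = rng.uniform(0.01, 0.2, size=5)
        uni = pool_univariate(y, v, method="dl")
        mv = pool_multivariate(y[:, None], v[:, None, None], method="mm")
        assert mv.pooled[0] == pytest.approx(uni.pooled[0], abs=1e-10)
        assert mv.Q == pytest.approx(uni.Q, abs=1e-10)
        assert float(np.ravel(mv.tau2)[0]) == pytest.approx(float(uni.tau2), abs=1e-10)

    def test_psi_estimate_is_psd(self, rng):
        ys, covs = self._random_inputs(rng, n=5, p=2)
        m = pool_multivariate(ys, covs, method="reml")
        assert np.linalg.eigvalsh(np.atleast_2d(m.tau2)).min() >= -1e-10

    def test_non_psd_input_rejected(self):
        bad = np.array([[[1.0, 2.0], [2.0, 1.0]]] * 2)
        with pytest.raises(ValueError):
            pool_multivariate(np.zeros((2, 2)), bad)


class TestPooledCurve:
    var_spec = SplineSpec((22.0, 26.0, 28.0), (15.0, 35.0))
    grid = np.arange(16.0, 34.0, 0.2)

    def test_homogeneous_pooling_reproduces_country_curve(self, rng):
        coef = rng.normal(scale=0.3, size=4)
        cov = 0.01 * np.eye(4)
        ys = np.tile(coef, (3, 1))
        covs = np.array([cov] * 3)
        m = pool_multivariate(ys, covs, method="fixed")
        pc = pooled_curve(m, self.var_spec, self.grid, 26.0)
        single = predict_curve(coef, cov, self.var_spec, self.grid, 26.0)
        np.testing.assert_allclose(pc.log_or, single.log_or, atol=1e-10)
        # OR at the center is exactly 1
        i = np.argmin(np.abs(pc.grid - 26.0))
        assert pc.log_or[i] == pytest.approx(0.0, abs=1e-10)

    def test_gls_variance_reduction(self, rng):
        """With Psi = 0 the pooled s.e. at every grid point is no larger
        than the largest country-specific s.e. there."""
        coefs = rng.normal(scale=0.3, size=(3, 4))
        covs = []
        for _ in range(3):
            A = rng.normal(size=(4, 4))
            covs.append(A @ A.T / 4 + 0.02 * np.eye(4))
        m = pool_multivariate(coefs, np.array(covs), method="fixed")
        pc = pooled_curve(m, self.var_spec, self.grid, 26.0)
        ses = [
            predict_curve(c, V, self.var_spec, self.grid, 26.0).se
            for c, V in zip(coefs, covs)
        ]
        assert np.all(pc.se <= np.max(ses, axis=0) + 1e-10)

    def test_projection_is_exact_linear_map(self, rng):
        """Re-expressing a curve on a shared basis reproduces its fitted
        values when the spaces coincide."""
        src = SplineSpec((23.0, 27.0), (15.0, 35.0))
        dst = SplineSpec((23.0, 27.0), (15.0, 35.0))  # same space, same knots
        coef = rng.normal(size=3)
        cov = 0.01 * np.eye(3)
        rc, rcov = project_curve_coefficients(
            coef, cov, src, dst, self.grid, from_center=26.0, to_center=26.0
        )
        a = predict_curve(coef, cov, src, self.grid, 26.0)
        b = predict_curve(rc, rcov, dst, self.grid, 26.0)
        np.testing.assert_allclose(a.log_or, b.log_or, atol=1e-8)
        np.testing.assert_allclose(a.se, b.se, atol=1e-8)

    def test_basis_mismatch_rejected(self, rng):
        m = pool_multivariate(rng.normal(size=(3, 3)),
                              np.array([np.eye(3) * 0.1] * 3), method="fixed")
        with pytest.raises(ValueError):
            pooled_curve(m, self.var_spec, self.grid, 26.0)  # dim 4 != 3
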