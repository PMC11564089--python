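"""Lagged exposure construction, percentiles, Magnus humidity and the
hottest-six-months scan."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heatperi.exposure import (
    MissingExposureError,
    TemperatureSeries,
    build_lag_vector,
    compute_percentiles,
    hottest_consecutive_months,
    lag_matrix,
    magnus_relative_humidity,
)


def make_series(t_mean, start="2021-01-01", hospital="h1"):
    t_mean = np.asarray(t_mean, dtype=float)
    dates = np.arange(
        np.datetime64(start, "D"), np.datetime64(start, "D") + np.timedelta64(t_mean.size, "D")
    )
    return TemperatureSeries(hospital, dates, t_mean, t_mean - 3, t_mean + 3, t_mean - 5)


class TestLagVector:
    def test_constant_series(self):
        s = make_series(np.full(30, 25.0))
        lv = build_lag_vector(s, "2021-01-20", 6)
        np.testing.assert_array_equal(lv.values, np.full(7, 25.0))
        assert len(lv) == 7

    def test_ramp_orientation(self):
        # temp on day d-k equals 20+k  ->  lag vector (20, 21, ..., 26)
        base = np.datetime64("2021-01-20")
        temps = np.zeros(30)
        start = np.datetime64("2021-01-01")
        for k in range(7):
            temps[(base - np.timedelta64(k, "D") - start).astype(int)] = 20 + k
        s = make_series(temps)
        lv = build_lag_vector(s, base, 6)
        np.testing.assert_array_equal(lv.values, np.arange(20.0, 27.0))

    def test_insufficient_history_raises(self):
        s = make_series(np.full(30, 25.0))
        with pytest.raises(MissingExposureError):
            build_lag_vector(s, "2021-01-03", 6)
        with pytest.raises(MissingExposureError):
            build_lag_vector(s, "2021-02-15", 6)  # past series end

    def test_matches_series_slicing(self):
        rng = np.random.default_rng(3)
        temps = rng.uniform(15, 35, size=60)
        s = make_series(temps)
        lv = build_lag_vector(s, "2021-02-01", 6)
        i = (np.datetime64("2021-02-01") - s.start).astype(int)
        np.testing.assert_array_equal(lv.values, temps[i - 6 : i + 1][::-1])

    def test_metric_routing(self):
        s = make_series(np.full(30, 25.0))
        assert build_lag_vector(s, "2021-01-20", 2, "max").values[0] == 28.0
        assert build_lag_vector(s, "2021-01-20", 2, "min").values[0] == 22.0

    def test_lag_matrix_batches(self):
        s = make_series(np.arange(40.0))
        dates = [np.datetime64("2021-01-10"), np.datetime64("2021-01-20")]
        M = lag_matrix(s, dates, 3)
        np.testing.assert_array_equal(M[0], [9, 8, 7, 6])
        np.testing.assert_array_equal(M[1], [19, 18, 17, 16])


class TestPercentiles:
    def test_linear_interpolation_convention(self):
        with pytest.warns(UserWarning):
            p = compute_percentiles(np.arange(1.0, 101.0), [0.75])
        assert p.values[0] == pytest.approx(75.25)

    def test_boundary_and_degenerate(self):
        vals = np.r_[np.arange(1.0, 366.0)]
        p = compute_percentiles(vals, [0.0, 1.0])
        assert (p.values[0], p.values[1]) == (1.0, 365.0)
        c = compute_percentiles(np.full(400, 7.0), [0.1, 0.5, 0.9])
        np.testing.assert_array_equal(c.values, [7.0, 7.0, 7.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_percentiles([], [0.5])

    @given(shift=st.floats(-30, 30), seed=st.integers(0, 100))
    def test_shift_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(25, 3, size=400)
        probs = [0.1, 0.5, 0.75, 0.99]
        base = compute_percentiles(vals, probs).values
        shifted = compute_percentiles(vals + shift, probs).values
        np.testing.assert_allclose(shifted, base + shift, atol=1e-9)


class TestMagnus:
    def test_saturation_is_100(self):
        assert magnus_relative_humidity(20.0, 20.0) == pytest.approx(100.0)
        assert magnus_relative_humidity(0.0, 0.0) == pytest.approx(100.0)

    def test_reference_value(self):
        assert magnus_relative_humidity(25.0, 20.0) == pytest.approx(73.8, abs=0.05)

    def test_monotone_in_dewpoint_and_bounded(self):
        t_dew = np.linspace(-10, 25, 100)
        rh = magnus_relative_humidity(np.full(100, 25.0), t_dew)
        assert np.all(np.diff(rh) > 0)
        assert np.all((rh > 0) & (rh <= 100))

    def test_supersaturation_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert magnus_relative_humidity(20.0, 25.0) == pytest.approx(100.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            magnus_relative_humidity(-250.0, -260.0)


class TestHottestMonths:
    def _sinusoid_series(self, peak_doy):
        dates = np.arange(np.datetime64("2021-01-01"), np.datetime64("2023-01-01"))
        doy = (dates - dates.astype("datetime64[Y]").astype("datetime64[D]")).astype(int) + 1
        t = 25 + 5 * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)
        return TemperatureSeries("h1", dates, t, t - 2, t + 2, t - 5)

    def test_january_peak_gives_november_april(self):
        s = self._sinusoid_series(15)
        window = hottest_consecutive_months(s)
        # exhaustive oracle over the 12 circular windows of monthly means
        months = s.dates.astype("datetime64[M]").astype(int) % 12 + 1
        mmeans = {m: s.t_mean[months == m].mean() for m in range(1, 13)}
        best = max(
            range(12),
            key=lambda st: np.mean([mmeans[(st + k) % 12 + 1] for k in range(6)]),
        )
        expected = tuple((best + k) % 12 + 1 for k in range(6))
        assert window == expected
        assert window == (11, 12, 1, 2, 3, 4)

    def test_constant_series_ties_to_january(self):
        dates = np.arange(np.datetime64("2021-01-01"), np.datetime64("2022-01-01"))
        t = np.full(dates.size, 20.0)
        s = TemperatureSeries("h1", dates, t, t, t, t)
        assert hottest_consecutive_months(s) == (1, 2, 3, 4, 5, 6)

    def test_constructed_block(self):
        dates = np.arange(np.datetime64("2021-01-01"), np.datetime64("2022-01-01"))
        months = dates.astype("datetime64[M]").astype(int) % 12 + 1
        t = np.where(np.isin(months, [6, 7, 8, 9, 10, 11]), 20.0, 10.0)
        s = TemperatureSeries("h1", dates, t, t, t, t)
        assert hottest_consecutive_months(s) == (6, 7, 8, 9, 10, 11)

    def test_requires_full_year(self):
        dates = np.arange(np.datetime64("2021-01-01"), np.datetime64("2021-06-01"))
        t = np.full(dates.size, 20.0)
        with pytest.raises(ValueError):
            hottest_consecutive_months(TemperatureSeries("h1", dates, t, t, t, t))


class TestSeriesValidation:
    def test_gap_rejected(self):
        dates = np.r_[
            np.arange(np.datetime64("2021-01-01"), np.datetime64("2021-01-10")),
            np.arange(np.datetime64("2021-01-12"), np.datetime64("2021-01-20")),
        ]
        t = np.full(dates.size, 20.0)
        with pytest.raises(ValueError):
            TemperatureSeries("h1", dates, t, t, t, t)

    def test_ordering_violation_rejected(self):
        dates = np.arange(np.datetime64("2021-01-01"), np.datetime64("2021-01-10"))
        t = np.full(dates.size, 20.0)
        with pytest.raises(ValueError):
            TemperatureSeries("h1", dates, t, t + 1, t + 2, t)  # t_min > t_mean
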