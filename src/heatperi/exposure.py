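"""Lagged exposure vectors, temperature percentiles, relative humidity and
season subsets derived from daily per-hospital temperature series."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "LagVector",
    "PercentileSet",
    "MissingExposureError",
    "build_lag_vector",
    "lag_matrix",
    "compute_percentiles",
    "magnus_relative_humidity",
    "hottest_consecutive_months",
    "read_temperature_table",
    "write_temperature_table",
]

# Magnus saturation-vapour-pressure constants (over water)
MAGNUS_ALPHA = 17.625
MAGNUS_BETA = 243.04  # deg C

_METRIC_COLS = {"mean": "t_mean", "min": "t_min", "max": "t_max", "dewpoint": "t_dewpoint"}


class MissingExposureError(KeyError):
    """A requested day is absent from the temperature series."""


@dataclass
class TemperatureSeries:
    """Contiguous daily weather values for one hospital (deg C)."""

    hospital_id: str
    dates: np.ndarray  # datetime64[D], strictly consecutive
    t_mean: np.ndarray
    t_min: np.ndarray
    t_max: np.ndarray
    t_dewpoint: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        for name in ("t_mean", "t_min", "t_max", "t_dewpoint"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.dates)
        if any(len(getattr(self, c)) != n for c in ("t_mean", "t_min", "t_max", "t_dewpoint")):
            raise ValueError("all value arrays must match the date vector length")
        if n > 1 and not np.all(np.diff(self.dates) == np.timedelta64(1, "D")):
            raise ValueError(f"dates of series {self.hospital_id!r} are not consecutive")
        if np.any(self.t_min > self.t_mean + 1e-9) or np.any(self.t_mean > self.t_max + 1e-9):
            raise ValueError(f"series {self.hospital_id!r} violates t_min <= t_mean <= t_max")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> np.datetime64:
        return self.dates[0]

    @property
    def end(self) -> np.datetime64:
        return self.dates[-1]

    def values(self, metric: str = "mean") -> np.ndarray:
        try:
            return getattr(self, _METRIC_COLS[metric])
        except KeyError:
            raise ValueError(f"unknown metric {metric!r}") from None

    def relative_humidity(self) -> np.ndarray:
        """Daily relative humidity (%) from mean and dew-point temperature."""
        return magnus_relative_humidity(self.t_mean, self.t_dewpoint)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hospital_id": self.hospital_id,
                "date": self.dates,
                "t_mean": self.t_mean,
                "t_min": self.t_min,
                "t_max": self.t_max,
                "t_dewpoint": self.t_dewpoint,
            }
        )


@dataclass(frozen=True)
class LagVector:
    """Exposure history for one reference date: element ``k`` is the metric
    value ``k`` days before ``reference_date`` (lag 0 = the date itself)."""

    reference_date: np.datetime64
    values: np.ndarray
    metric: str = "mean"

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PercentileSet:
    """Empirical temperature quantiles with their probabilities."""

    probs: np.ndarray
    values: np.ndarray
    source_scope: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        order = np.argsort(self.probs)
        if np.any(np.diff(self.values[order]) < -1e-9):
            raise ValueError("percentile values must be non-decreasing in probability")

    def at(self, p: float) -> float:
        """Value for probability ``p`` (must be one of ``probs``)."""
        idx = np.flatnonzero(np.isclose(self.probs, p))
        if idx.size == 0:
            raise KeyError(f"probability {p} not in percentile set")
        return float(self.values[idx[0]])


def lag_matrix(series: TemperatureSeries, dates, L: int, metric: str = "mean") -> np.ndarray:
    """Exposure histories for many reference dates at once.

    Returns ``(len(dates), L+1)`` with column ``k`` the metric value ``k``
    days before each date.  Raises MissingExposureError if any date in
    ``[date - L, date]`` falls outside the series.
    """
    dates = np.asarray(dates, dtype="datetime64[D]")
    pos = (dates - series.start).astype(int)
    bad = (pos - L < 0) | (pos >= len(series))
    if bad.any():
        first = dates[bad][0]
        raise MissingExposureError(
            f"series {series.hospital_id!r} does not cover lags 0..{L} for date {first}"
        )
    vals = series.values(metric)
    offsets = np.arange(L + 1)
    return vals[pos[:, None] - offsets[None, :]]


def build_lag_vector(series: TemperatureSeries, date, L: int, metric: str = "mean") -> LagVector:
    """Exposure history for one date: values at lags ``0..L`` (lag k = k days
    earlier)."""
    date = np.datetime64(date, "D")
    row = lag_matrix(series, [date], L, metric)[0]
    return LagVector(reference_date=date, values=row, metric=metric)


def compute_percentiles(values, probs, source_scope: str = "") -> PercentileSet:
    """Empirical quantiles by linear interpolation of order statistics
    (the ``h = (n-1)p + 1`` convention; values 1..100 at p=0.75 give 75.25).

    At least a year of daily values is expected so that the annual
    distribution is fully represented.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute percentiles of an empty sample")
    if values.size < 365:
        warnings.warn(
            f"percentiles computed on {values.size} < 365 daily values; "
            "annual distribution may be incomplete",
            stacklevel=2,
        )
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    q = np.quantile(values, probs, method="linear")
    return PercentileSet(probs=probs, values=q, source_scope=source_scope)


def magnus_relative_humidity(t_air, t_dew):
    """Relative humidity (%) from air and dew-point temperature (deg C) via
    the Magnus formula:

        RH = 100 * exp( a*Td/(b+Td) - a*T/(b+T) ),  a = 17.625, b = 243.04.

    Saturated air (``t_dew == t_air``) gives exactly 100%.  ``t_dew > t_air``
    is physically supersaturated; the result is clamped at 100 with a warning.
    """
    t_air = np.asarray(t_air, dtype=float)
    t_dew = np.asarray(t_dew, dtype=float)
    if np.any(t_air <= -MAGNUS_BETA) or np.any(t_dew <= -MAGNUS_BETA):
        raise ValueError(f"temperatures must exceed -{MAGNUS_BETA} deg C")
    gamma = MAGNUS_ALPHA * t_dew / (MAGNUS_BETA + t_dew) - MAGNUS_ALPHA * t_air / (
        MAGNUS_BETA + t_air
    )
    rh = 100.0 * np.exp(gamma)
    if np.any(rh > 100.0 + 1e-9):
        warnings.warn("dew point above air temperature; RH clamped at 100%", stacklevel=2)
    rh = np.minimum(rh, 100.0)
    return float(rh) if rh.ndim == 0 else rh


def hottest_consecutive_months(series_or_frames) -> tuple[int, ...]:
    """The 6 consecutive calendar months (circular window) with the highest
    mean daily mean-temperature; ties broken by the earliest starting month.

    Accepts one TemperatureSeries or an iterable of them (pooled).  Requires
    at least a full year of data so all 12 months are represented.
    """
    if isinstance(series_or_frames, TemperatureSeries):
        series_list = [series_or_frames]
    else:
        series_list = list(series_or_frames)
    months = np.concatenate(
        [s.dates.astype("datetime64[M]").astype(int) % 12 + 1 for s in series_list]
    )
    temps = np.concatenate([s.t_mean for s in series_list])
    monthly = pd.Series(temps).groupby(months).mean()
    if len(monthly) < 12:
        raise ValueError("hottest-month scan needs all 12 calendar months of data")
    means = monthly.sort_index().to_numpy()  # index 0 -> January
    best_start, best_val = 0, -np.inf
    for start in range(12):
        window = means[(np.arange(start, start + 6)) % 12]
        val = window.mean()
        if val > best_val + 1e-12:
            best_start, best_val = start, val
    return tuple((best_start + k) % 12 + 1 for k in range(6))


def read_temperature_table(path) -> dict[str, TemperatureSeries]:
    """Read a delimited temperature table (columns hospital_id, date,
    t_mean, t_min, t_max, t_dewpoint; ISO-8601 dates) into one
    TemperatureSeries per hospital."""
    df = pd.read_csv(path, parse_dates=["date"])
    out: dict[str, TemperatureSeries] = {}
    for hid, grp in df.groupby("hospital_id", sort=True):
        grp = grp.sort_values("date")
        out[str(hid)] = TemperatureSeries(
            hospital_id=str(hid),
            dates=grp["date"].to_numpy().astype("datetime64[D]"),
            t_mean=grp["t_mean"].to_numpy(),
            t_min=grp["t_min"].to_numpy(),
            t_max=grp["t_max"].to_numpy(),
            t_dewpoint=grp["t_dewpoint"].to_numpy(),
        )
    return out


def write_temperature_table(series_by_hospital: dict[str, TemperatureSeries], path) -> None:
    frames = [series_by_hospital[h].to_frame() for h in sorted(series_by_hospital)]
    df = pd.concat(frames, ignore_index=True)
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.4f")
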