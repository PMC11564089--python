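"""Synthetic birth registries and daily temperature series with known,
configurable heat-mortality effects.

The generator emulates a multi-country hospital birth registry (four
sub-Saharan climates, four hospitals each) so that every downstream stage —
referent selection, crossbasis regression, curve reduction, pooling — can be
tested against an injected ground truth.

Temperature is a seasonal sinusoid plus AR(1) noise: the simplest process
with realistic day-to-day autocorrelation, so control-day exposures
correlate with case-day exposures as in real series.  The mortality risk
model applies a transfer function to the lag-weighted mean temperature of
the week before birth; with the default linear-above-threshold transfer the
true cumulative OR between any two temperatures above the threshold is
available in closed form, which makes exact recovery tests possible.
Covariates are drawn independently of exposure: the case-crossover design's
claim is confounder invariance within a month, not covariate realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit

from .design import BIRTH_COLUMNS, OUTCOME_COLUMNS
from .exposure import TemperatureSeries, compute_percentiles

__all__ = [
    "SimulationConfig",
    "BirthRecord",
    "COUNTRY_PRESETS",
    "simulate_temperature",
    "simulate_births",
    "simulate_country",
    "simulate_study",
    "as_records",
]

# Covariate prevalences, loosely calibrated to a four-country African
# hospital-birth population (order-of-magnitude realism only).
DEFAULT_COVARIATE_PREVALENCE: dict[str, float] = {
    "maternal_age_ge35": 0.12,
    "parity_ge2": 0.64,
    "hiv_positive": 0.03,
    "hypertensive_disorder": 0.08,
    "female_infant": 0.51,
    "preterm": 0.13,
    "low_birth_weight": 0.13,
    "prolonged_obstructed_labor": 0.08,
    "antepartum_hemorrhage": 0.015,
    "referred": 0.20,
}

# Given a perinatal death: probability it is a stillbirth (the rest are
# deaths within 24 h of a live birth); given a stillbirth: probability it is
# antepartum (macerated) rather than intrapartum (fresh).
P_STILLBIRTH_GIVEN_DEATH = 0.88
P_ANTEPARTUM_GIVEN_STILLBIRTH = 0.56


@dataclass(frozen=True)
class BirthRecord:
    """One delivery: date, hospital, outcome flags and effect-modifier flags.

    Invariants: ``stillbirth = antepartum | intrapartum`` (subtypes mutually
    exclusive); ``perinatal_death = stillbirth | early_neonatal_death_24h``;
    a neonatal death implies a live birth (not a stillbirth).
    """

    hospital_id: str
    country: str
    birth_date: np.datetime64
    stillbirth: bool
    antepartum_stillbirth: bool
    intrapartum_stillbirth: bool
    early_neonatal_death_24h: bool
    perinatal_death: bool
    maternal_age_ge35: bool
    parity_ge2: bool
    hiv_positive: bool
    hypertensive_disorder: bool
    female_infant: bool
    preterm: bool
    low_birth_weight: bool
    prolonged_obstructed_labor: bool
    antepartum_hemorrhage: bool
    referred: bool

    def __post_init__(self) -> None:
        if self.stillbirth != (self.antepartum_stillbirth or self.intrapartum_stillbirth):
            raise ValueError("stillbirth flag must equal the union of its subtypes")
        if self.antepartum_stillbirth and self.intrapartum_stillbirth:
            raise ValueError("stillbirth subtypes are mutually exclusive")
        if self.perinatal_death != (self.stillbirth or self.early_neonatal_death_24h):
            raise ValueError("perinatal_death must equal stillbirth | neonatal death")
        if self.early_neonatal_death_24h and self.stillbirth:
            raise ValueError("a neonatal death implies a live birth")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generating process for one country.

    Temperature: ``t_mean(d) = temp_annual_mean + seasonal_amplitude *
    cos(2 pi (doy - seasonal_peak_day)/365.25) + AR(1)``, with the AR(1)
    marginal s.d. equal to ``temp_annual_sd`` unless ``ar1_noise_sd`` (the
    innovation s.d.) is given explicitly.  Outcome risk: logit(p) =
    logit(baseline_outcome_prob) + transfer(lag-weighted weekly mean), where
    the default transfer is linear above the series' 75th percentile with a
    slope chosen so the cumulative OR between the 99th and 75th percentiles
    equals ``true_cumulative_or`` (or ``effect_logor_per_unit`` directly).
    """

    country_label: str = "synthetic"
    n_hospitals: int = 4
    start_date: str = "2021-07-01"
    end_date: str = "2023-12-31"
    temp_annual_mean: float = 25.0
    temp_annual_sd: float = 1.0
    seasonal_amplitude: float = 2.0
    seasonal_peak_day: int = 46
    ar1_coefficient: float = 0.7
    ar1_noise_sd: float | None = None
    diurnal_half_range: float = 4.0
    dewpoint_depression: float = 4.0
    births_per_day_mean: float = 25.0
    baseline_outcome_prob: float = 0.04
    effect_logor_per_unit: float | None = None
    true_cumulative_or: float | None = None
    transfer_temps: tuple[float, ...] | None = None  # tabulated transfer fn
    transfer_logor: tuple[float, ...] | None = None
    lag_weights: tuple[float, ...] = (1 / 7,) * 7
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be strictly inside (-1, 1)")
        if not 0.0 < self.baseline_outcome_prob < 1.0:
            raise ValueError("baseline_outcome_prob must be in (0, 1)")
        lw = np.asarray(self.lag_weights, dtype=float)
        if np.any(lw < 0) or abs(lw.sum() - 1.0) > 1e-12:
            raise ValueError("lag_weights must be non-negative and sum to 1 (tol 1e-12)")
        if (self.transfer_temps is None) != (self.transfer_logor is None):
            raise ValueError("transfer_temps and transfer_logor must be given together")

    @property
    def lag_window(self) -> int:
        return len(self.lag_weights) - 1

    def innovation_sd(self) -> float:
        if self.ar1_noise_sd is not None:
            return float(self.ar1_noise_sd)
        return float(self.temp_annual_sd * np.sqrt(1.0 - self.ar1_coefficient**2))


# Country climates and outcome prevalences calibrated so the implied
# birth-week mean temperature distribution approximately matches four
# sub-Saharan hospital networks (Benin hottest/most stable, Malawi coolest/
# most seasonal), with seasonal amplitude + AR(1) marginal s.d. decomposing
# the target weekly s.d.
COUNTRY_PRESETS: dict[str, SimulationConfig] = {
    "benin": SimulationConfig(
        country_label="benin",
        temp_annual_mean=26.9,
        temp_annual_sd=0.8,
        seasonal_amplitude=1.5,
        seasonal_peak_day=46,
        diurnal_half_range=2.4,
        baseline_outcome_prob=0.080,
        births_per_day_mean=7.2,
        seed=1,
    ),
    "malawi": SimulationConfig(
        country_label="malawi",
        temp_annual_mean=20.1,
        temp_annual_sd=1.9,
        seasonal_amplitude=3.6,
        seasonal_peak_day=330,
        diurnal_half_range=5.0,
        baseline_outcome_prob=0.025,
        births_per_day_mean=13.8,
        seed=2,
    ),
    "tanzania": SimulationConfig(
        country_label="tanzania",
        temp_annual_mean=24.8,
        temp_annual_sd=1.0,
        seasonal_amplitude=2.0,
        seasonal_peak_day=46,
        diurnal_half_range=5.0,
        baseline_outcome_prob=0.020,
        births_per_day_mean=6.5,
        seed=3,
    ),
    "uganda": SimulationConfig(
        country_label="uganda",
        temp_annual_mean=22.1,
        temp_annual_sd=0.65,
        seasonal_amplitude=0.9,
        seasonal_peak_day=60,
        diurnal_half_range=3.5,
        baseline_outcome_prob=0.054,
        births_per_day_mean=10.2,
        seed=4,
    ),
}


def _date_range(config: SimulationConfig, lead_days: int) -> np.ndarray:
    start = np.datetime64(config.start_date, "D") - np.timedelta64(lead_days, "D")
    end = np.datetime64(config.end_date, "D")
    if end <= start:
        raise ValueError("end_date must be after start_date")
    return np.arange(start, end + np.timedelta64(1, "D"))


def simulate_temperature(
    config: SimulationConfig,
    hospital_id: str | None = None,
    rng: np.random.Generator | None = None,
    lead_days: int | None = None,
) -> TemperatureSeries:
    """One hospital's daily series: seasonal sinusoid + AR(1) mean, with
    min/max at +/- the diurnal half-range (plus small noise, ordering kept)
    and dew point below the mean.  Deterministic given config.seed (or an
    explicit rng)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lead = config.lag_window if lead_days is None else lead_days
    dates = _date_range(config, lead)
    if dates.size < 365:
        raise ValueError(
            "temperature simulation needs at least one full year "
            "(annual percentiles are undefined on partial seasonality)"
        )
    doy = (dates - dates.astype("datetime64[Y]").astype("datetime64[D]")).astype(int) + 1
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_peak_day) / 365.25
    )
    sd_in = config.innovation_sd()
    if sd_in > 0:
        eps = rng.normal(0.0, sd_in, size=dates.size)
        # start the recursion at the stationary distribution
        eps[0] = rng.normal(0.0, sd_in / np.sqrt(1 - config.ar1_coefficient**2))
        ar = lfilter([1.0], [1.0, -config.ar1_coefficient], eps)
    else:
        ar = np.zeros(dates.size)
    t_mean = config.temp_annual_mean + seasonal + ar
    jitter = rng.normal(0.0, 0.2, size=(2, dates.size)) if sd_in > 0 else np.zeros((2, dates.size))
    t_min = np.minimum(t_mean - config.diurnal_half_range + jitter[0], t_mean)
    t_max = np.maximum(t_mean + config.diurnal_half_range + jitter[1], t_mean)
    dew_noise = rng.normal(0.0, 0.5, size=dates.size) if sd_in > 0 else np.zeros(dates.size)
    t_dew = np.minimum(t_mean - config.dewpoint_depression + dew_noise, t_mean)
    return TemperatureSeries(
        hospital_id=hospital_id or f"{config.country_label}_h1",
        dates=dates,
        t_mean=t_mean,
        t_min=t_min,
        t_max=t_max,
        t_dewpoint=t_dew,
    )


def _transfer_logor(config: SimulationConfig, weekly_mean: np.ndarray,
                    reference_values: np.ndarray) -> np.ndarray:
    """Log-odds effect term at each birth's lag-weighted weekly mean."""
    if config.transfer_temps is not None:
        out = np.interp(
            weekly_mean, np.asarray(config.transfer_temps), np.asarray(config.transfer_logor)
        )
    else:
        q = compute_percentiles(reference_values, [0.75, 0.99], "effect calibration")
        q75, q99 = q.values
        if config.effect_logor_per_unit is not None:
            slope = config.effect_logor_per_unit
        elif config.true_cumulative_or is not None:
            if q99 <= q75:
                raise ValueError("degenerate temperature distribution: q99 <= q75")
            slope = np.log(config.true_cumulative_or) / (q99 - q75)
        else:
            slope = 0.0
        out = slope * np.maximum(0.0, weekly_mean - q75)
    if not np.all(np.isfinite(out)):
        raise ValueError("effect specification produced non-finite log-odds")
    return out


def simulate_births(
    config: SimulationConfig,
    series: TemperatureSeries,
    rng: np.random.Generator | None = None,
    reference_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Birth registry for one hospital: daily Poisson birth counts; outcome
    Bernoulli with logit = logit(baseline) + transfer(lag-weighted weekly
    mean temperature).  ``reference_values`` (default: the series' own daily
    means) define the percentiles used to calibrate the effect slope.

    Returns a DataFrame with exactly the BirthRecord columns.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    L = config.lag_window
    start = np.datetime64(config.start_date, "D")
    end = np.datetime64(config.end_date, "D")
    if series.start > start - np.timedelta64(L, "D") or series.end < end:
        raise ValueError("temperature series must cover the birth range plus the lag window")
    days = np.arange(start, end + np.timedelta64(1, "D"))
    counts = rng.poisson(config.births_per_day_mean, size=days.size)
    birth_dates = np.repeat(days, counts)
    n = birth_dates.size

    lw = np.asarray(config.lag_weights)
    pos = (days - series.start).astype(int)
    win = series.t_mean[pos[:, None] - np.arange(L + 1)[None, :]]
    weekly_mean_by_day = win @ lw
    weekly_mean = np.repeat(weekly_mean_by_day, counts)

    ref = series.t_mean if reference_values is None else reference_values
    eff = _transfer_logor(config, weekly_mean, ref)
    p = expit(logit(config.baseline_outcome_prob) + eff)
    death = rng.random(n) < p
    u_sb = rng.random(n)
    stillbirth = death & (u_sb < P_STILLBIRTH_GIVEN_DEATH)
    antepartum = stillbirth & (rng.random(n) < P_ANTEPARTUM_GIVEN_STILLBIRTH)
    intrapartum = stillbirth & ~antepartum
    neonatal = death & ~stillbirth

    data = {
        "hospital_id": np.full(n, series.hospital_id),
        "country": np.full(n, config.country_label),
        "birth_date": birth_dates,
        "stillbirth": stillbirth,
        "antepartum_stillbirth": antepartum,
        "intrapartum_stillbirth": intrapartum,
        "early_neonatal_death_24h": neonatal,
        "perinatal_death": death,
    }
    for name, prev in config.covariate_prevalence.items():
        data[name] = rng.random(n) < prev
    df = pd.DataFrame(data)
    return df[list(BIRTH_COLUMNS)]


def simulate_country(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, TemperatureSeries]]:
    """All hospitals of one country: per-hospital series (independent AR
    noise, shared climate) and the pooled birth registry.  The effect slope
    is calibrated on the country-pooled daily mean distribution, matching
    how the analysis pipeline computes its percentiles."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    series_by_hospital: dict[str, TemperatureSeries] = {}
    for h in range(config.n_hospitals):
        hid = f"{config.country_label}_h{h + 1}"
        series_by_hospital[hid] = simulate_temperature(config, hospital_id=hid, rng=rng)
    pooled = np.concatenate([s.t_mean for s in series_by_hospital.values()])
    frames = [
        simulate_births(config, s, rng=rng, reference_values=pooled)
        for s in series_by_hospital.values()
    ]
    births = pd.concat(frames, ignore_index=True)
    return births, series_by_hospital


def simulate_study(
    presets: dict[str, SimulationConfig] | None = None,
    seed: int = 0,
    **overrides,
) -> tuple[pd.DataFrame, dict[str, TemperatureSeries]]:
    """A full multi-country study (default: the four country presets).

    ``overrides`` replace fields on every preset (e.g.
    ``true_cumulative_or=1.5``, ``births_per_day_mean=20``).  The master
    seed spawns one independent stream per country, so the whole study is
    deterministic in ``seed``.
    """
    presets = dict(COUNTRY_PRESETS) if presets is None else presets
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(presets))
    all_births = []
    all_series: dict[str, TemperatureSeries] = {}
    for child, (name, cfg) in zip(children, sorted(presets.items())):
        cfg = replace(cfg, **overrides) if overrides else cfg
        births, series = simulate_country(cfg, rng=np.random.default_rng(child))
        all_births.append(births)
        all_series.update(series)
    return pd.concat(all_births, ignore_index=True), all_series


def simulate_u_shape_study(
    seed: int = 0,
    curvature: float = 0.08,
    mmt_percentile: float = 0.40,
    presets: dict[str, SimulationConfig] | None = None,
    **overrides,
) -> tuple[pd.DataFrame, dict[str, TemperatureSeries], dict[str, dict[str, float]]]:
    """Multi-country study with a U-shaped risk transfer function.

    Risk is quadratic in the weekly mean temperature,
    ``curvature * (t - t_mmt)^2`` per country, with the true
    minimum-mortality temperature ``t_mmt`` placed at ``mmt_percentile`` of
    the country's pooled daily mean distribution (temperatures are
    generated first, then the transfer is tabulated on them).  Returns the
    births, the series, and per-country ground truth: the absolute MMT, the
    75th percentile, and the MMT on the relative (deg C above the 75th
    percentile) scale used by the pooled curve.
    """
    presets = dict(COUNTRY_PRESETS) if presets is None else presets
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(presets))
    all_births = []
    all_series: dict[str, TemperatureSeries] = {}
    truth: dict[str, dict[str, float]] = {}
    for child, (name, cfg) in zip(children, sorted(presets.items())):
        cfg = replace(cfg, **overrides) if overrides else cfg
        rng = np.random.default_rng(child)
        series = {
            f"{cfg.country_label}_h{h + 1}": simulate_temperature(
                cfg, hospital_id=f"{cfg.country_label}_h{h + 1}", rng=rng
            )
            for h in range(cfg.n_hospitals)
        }
        pooled = np.concatenate([s.t_mean for s in series.values()])
        t_mmt = float(np.quantile(pooled, mmt_percentile))
        q75 = float(np.quantile(pooled, 0.75))
        grid = np.linspace(pooled.min() - 10.0, pooled.max() + 10.0, 513)
        cfg_u = replace(
            cfg,
            transfer_temps=tuple(grid),
            transfer_logor=tuple(curvature * (grid - t_mmt) ** 2),
        )
        frames = [simulate_births(cfg_u, s, rng=rng) for s in series.values()]
        all_births.append(pd.concat(frames, ignore_index=True))
        all_series.update(series)
        truth[name] = {"mmt": t_mmt, "q75": q75, "mmt_rel": t_mmt - q75}
    return pd.concat(all_births, ignore_index=True), all_series, truth


def as_records(births: pd.DataFrame) -> list[BirthRecord]:
    """Materialize BirthRecord objects (validates the logical invariants)."""
    recs = []
    for row in births.itertuples(index=False):
        d = row._asdict()
        d["birth_date"] = np.datetime64(pd.Timestamp(d["birth_date"]).date(), "D")
        recs.append(BirthRecord(**{k: d[k] for k in BirthRecord.__dataclass_fields__}))
    return recs
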