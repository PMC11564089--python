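"""End-to-end study orchestration: per-country DLNM case-crossover fits for
each outcome, two-stage pooling, effect-modification strata, and the
sensitivity-analysis grid."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .basis import CrossBasisSpec, SplineSpec, default_crossbasis
from .clogit import FitResult, ZeroInformationError, fit_conditional_logistic, wald_interval
from .curve import (
    ReducedCurve,
    cumulative_contrast_vector,
    find_mmt,
    or_at,
    predict_curve,
    reduce_to_cumulative,
)
from .design import OUTCOME_COLUMNS, build_strata
from .exposure import (
    PercentileSet,
    TemperatureSeries,
    compute_percentiles,
    hottest_consecutive_months,
)
from .meta import (
    MetaResult,
    pool_multivariate,
    pool_univariate,
    pooled_curve,
    project_curve_coefficients,
)

__all__ = [
    "AnalysisConfig",
    "CountryOutcomeResult",
    "CountryResult",
    "StudyResult",
    "run_country",
    "run_study",
    "sensitivity_suite",
    "SENSITIVITY_KNOT_VARIANTS",
]

MODIFIER_COLUMNS = (
    "maternal_age_ge35",
    "parity_ge2",
    "hiv_positive",
    "hypertensive_disorder",
    "female_infant",
    "preterm",
    "low_birth_weight",
    "prolonged_obstructed_labor",
    "antepartum_hemorrhage",
)

Z95 = 1.959963984540054


@dataclass(frozen=True)
class AnalysisConfig:
    """Study configuration (defaults reproduce the primary analysis:
    lag 0-6 daily mean temperature, var-spline knots at the 10th/75th/90th
    percentiles, three log-spaced lag knots, OR contrasting the 99th against
    the 75th percentile of the annual distribution)."""

    outcomes: tuple[str, ...] = ("perinatal_death",)
    metric: str = "mean"
    lag_window: int = 6
    var_knot_percentiles: tuple[float, ...] = (0.10, 0.75, 0.90)
    lag_knots: int = 3
    contrast: tuple[float, float] = (0.99, 0.75)  # (target, reference)
    season_filter: str = "all"  # or "hottest6"
    referral_filter: str = "all"  # or "exclude_referred"
    humidity_adjust: bool = False
    modifier: str | None = None
    recompute_percentiles_in_season: bool = False
    curve_grid_step: float = 0.1
    mmt_band: tuple[float, float] = (0.01, 0.99)  # percentile band
    seed: int = 0

    def __post_init__(self) -> None:
        target, reference = self.contrast
        if not (0.0 < reference < target < 1.0):
            raise ValueError("contrast percentiles must satisfy 0 < reference < target < 1")
        for o in self.outcomes:
            if o not in OUTCOME_COLUMNS:
                raise ValueError(f"unknown outcome {o!r}")
        if self.metric not in ("mean", "min", "max"):
            raise ValueError(f"metric must be mean/min/max, got {self.metric!r}")
        if self.lag_window not in (0, 1, 2, 6):
            raise ValueError("lag_window must be one of 0, 1, 2, 6")
        if self.season_filter not in ("all", "hottest6"):
            raise ValueError("season_filter must be 'all' or 'hottest6'")
        if self.referral_filter not in ("all", "exclude_referred"):
            raise ValueError("referral_filter must be 'all' or 'exclude_referred'")
        if self.modifier is not None and self.modifier not in MODIFIER_COLUMNS:
            raise ValueError(f"modifier must be one of {MODIFIER_COLUMNS}")

    def to_dict(self) -> dict:
        return {
            "outcomes": list(self.outcomes),
            "metric": self.metric,
            "lag_window": self.lag_window,
            "var_knot_percentiles": list(self.var_knot_percentiles),
            "lag_knots": self.lag_knots,
            "contrast": list(self.contrast),
            "season_filter": self.season_filter,
            "referral_filter": self.referral_filter,
            "humidity_adjust": self.humidity_adjust,
            "modifier": self.modifier,
            "recompute_percentiles_in_season": self.recompute_percentiles_in_season,
            "curve_grid_step": self.curve_grid_step,
            "mmt_band": list(self.mmt_band),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("outcomes", "var_knot_percentiles", "contrast", "mmt_band"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class CountryOutcomeResult:
    country: str
    outcome: str
    n_cases: int
    n_strata_used: int
    n_excluded_missing_exposure: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    log_or_var: float
    fit: FitResult
    reduced_coefficients: np.ndarray
    reduced_covariance: np.ndarray
    curve: ReducedCurve | None = None
    mmt: float | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class CountryResult:
    country: str
    percentiles: PercentileSet
    var_spec: SplineSpec
    crossbasis: CrossBasisSpec
    outcomes: dict[str, CountryOutcomeResult] = field(default_factory=dict)
    skipped_outcomes: dict[str, str] = field(default_factory=dict)
    hottest_months: tuple[int, ...] | None = None
    metric_values: np.ndarray | None = None  # pooled daily values, percentile scope


@dataclass
class PooledOutcome:
    meta: MetaResult
    odds_ratio: float
    ci_low: float
    ci_high: float
    curve_meta: MetaResult | None = None
    curve: ReducedCurve | None = None
    common_var_spec: SplineSpec | None = None


@dataclass
class StudyResult:
    per_country: dict[str, CountryResult]
    pooled: dict[str, PooledOutcome]
    config: AnalysisConfig
    seed: int
    version: str = __version__
    warnings: list[str] = field(default_factory=list)
    modifier_strata: dict[bool, "StudyResult"] | None = None


_PCT_KEYS = (0.01, 0.10, 0.25, 0.50, 0.75, 0.90, 0.99)


def _country_percentiles(
    series_list: list[TemperatureSeries], config: AnalysisConfig, scope: str
) -> tuple[PercentileSet, np.ndarray]:
    values = np.concatenate([s.values(config.metric) for s in series_list])
    probs = sorted(
        set(_PCT_KEYS)
        | set(config.var_knot_percentiles)
        | set(config.contrast)
        | set(config.mmt_band)
    )
    return compute_percentiles(values, probs, scope), values


def _curve_grid(q_lo: float, q_hi: float, center: float, step: float) -> np.ndarray:
    grid = np.arange(q_lo, q_hi + step / 2, step)
    return np.unique(np.round(np.concatenate([grid, [center]]), 10))


def run_country(
    births: pd.DataFrame,
    series_by_hospital: dict[str, TemperatureSeries],
    config: AnalysisConfig,
    country: str | None = None,
    curves: bool = True,
) -> CountryResult:
    """First-stage analysis for one country: annual percentiles, strata,
    crossbasis fit, percentile-contrast OR, cumulative curve and MMT per
    outcome.  Outcomes with fewer than two informative strata are skipped
    with a recorded warning."""
    if country is not None and "country" in births.columns:
        births = births.loc[births["country"] == country]
    else:
        country = country or str(births["country"].iloc[0])
    hospitals = sorted(set(births["hospital_id"].astype(str)))
    missing = [h for h in hospitals if h not in series_by_hospital]
    if missing:
        raise KeyError(f"no temperature series for hospital(s): {missing}")
    series_list = [series_by_hospital[h] for h in hospitals]

    pct, pooled_values = _country_percentiles(
        series_list, config, f"{country}: pooled {config.metric} over study period"
    )
    hottest = None
    if config.season_filter == "hottest6":
        hottest = hottest_consecutive_months(series_list)
        months = pd.to_datetime(births["birth_date"]).dt.month
        births = births.loc[months.isin(hottest)]
        if config.recompute_percentiles_in_season:
            sel = np.concatenate(
                [
                    s.values(config.metric)[
                        np.isin(s.dates.astype("datetime64[M]").astype(int) % 12 + 1, hottest)
                    ]
                    for s in series_list
                ]
            )
            pct = compute_percentiles(
                sel, pct.probs, f"{country}: hottest-six-months {config.metric}"
            )
    if config.referral_filter == "exclude_referred":
        births = births.loc[~births["referred"].astype(bool)]

    var_knots = tuple(pct.at(p) for p in config.var_knot_percentiles)
    boundary = (float(pooled_values.min()), float(pooled_values.max()))
    spec = default_crossbasis(var_knots, boundary, L=config.lag_window,
                              n_lag_knots=config.lag_knots)

    q_target, q_ref = pct.at(config.contrast[0]), pct.at(config.contrast[1])
    result = CountryResult(
        country=country,
        percentiles=pct,
        var_spec=spec.var_spec,
        crossbasis=spec,
        hottest_months=hottest,
        metric_values=pooled_values,
    )

    from .basis import crossbasis_matrix  # local import avoids cycle at module load

    for outcome in config.outcomes:
        strata = build_strata(
            births,
            series_by_hospital,
            outcome,
            L=config.lag_window,
            metric=config.metric,
            with_humidity=config.humidity_adjust,
        )
        if strata.n_strata < 2:
            result.skipped_outcomes[outcome] = (
                f"only {strata.n_strata} stratum/strata after exclusions"
            )
            continue
        X = crossbasis_matrix(strata.lag_temps, spec)
        extra = None
        rh_spec = None
        if config.humidity_adjust:
            rh_all = np.concatenate([s.relative_humidity() for s in series_list])
            rh_pct = compute_percentiles(rh_all, [0.10, 0.75, 0.90], f"{country}: RH")
            rh_var = SplineSpec(
                tuple(rh_pct.values), (float(rh_all.min()), float(rh_all.max()))
            )
            rh_spec = default_crossbasis(
                rh_var.internal_knots, rh_var.boundary_knots,
                L=config.lag_window, n_lag_knots=config.lag_knots,
            )
            extra = crossbasis_matrix(strata.rh_lags, rh_spec)
        try:
            fit = fit_conditional_logistic(X, strata.is_case, strata.stratum_id,
                                           extra_columns=extra)
        except ZeroInformationError as exc:
            result.skipped_outcomes[outcome] = str(exc)
            continue
        reduced, reduced_cov = reduce_to_cumulative(fit, spec)
        orr, lo, hi = or_at(reduced, reduced_cov, spec.var_spec, q_target, q_ref)
        contrast = cumulative_contrast_vector(spec, q_target, q_ref)
        log_or = float(contrast @ fit.coefficients[: spec.dim])
        log_or_var = float(
            contrast @ fit.covariance[: spec.dim, : spec.dim] @ contrast
        )
        res = CountryOutcomeResult(
            country=country,
            outcome=outcome,
            n_cases=strata.n_strata,
            n_strata_used=fit.n_strata_used,
            n_excluded_missing_exposure=strata.n_excluded_missing_exposure,
            odds_ratio=orr,
            ci_low=lo,
            ci_high=hi,
            log_or=log_or,
            log_or_var=log_or_var,
            fit=fit,
            reduced_coefficients=reduced,
            reduced_covariance=reduced_cov,
        )
        if curves:
            grid = _curve_grid(
                pct.at(config.mmt_band[0]), pct.at(config.mmt_band[1]),
                q_ref, config.curve_grid_step,
            )
            res.curve = predict_curve(reduced, reduced_cov, spec.var_spec, grid, q_ref)
            res.mmt = find_mmt(
                res.curve, (pct.at(config.mmt_band[0]), pct.at(config.mmt_band[1]))
            )
        result.outcomes[outcome] = res
    return result


def _pool_outcome_curves(
    country_results: list[CountryOutcomeResult],
    per_country: dict[str, CountryResult],
    config: AnalysisConfig,
) -> tuple[MetaResult, ReducedCurve, SplineSpec]:
    """Multivariate pooling of reduced curves on a common basis.

    Countries differ in their deg-C knots, so curves are aligned on the
    relative scale (deg C above each country's reference percentile) and
    projected onto a shared natural-spline basis with knots at the pooled
    relative distribution's configured percentiles.
    """
    ref_p = config.contrast[1]
    rel_values = []
    for r in country_results:
        cr = per_country[r.country]
        ref_c = cr.percentiles.at(ref_p)
        if cr.metric_values is not None:
            rel_values.append(cr.metric_values - ref_c)
        else:
            rel_values.append(
                np.array([cr.percentiles.at(p) for p in cr.percentiles.probs]) - ref_c
            )
    all_rel = np.concatenate(rel_values)
    knots = tuple(np.quantile(all_rel, config.var_knot_percentiles))
    lo = float(min(v.min() for v in rel_values))
    hi = float(max(v.max() for v in rel_values))
    common = SplineSpec(knots, (lo, hi))
    grid = _curve_grid(lo, hi, 0.0, config.curve_grid_step)
    ys, covs = [], []
    for r in country_results:
        pct = per_country[r.country].percentiles
        ref_c = pct.at(ref_p)
        rc, rcov = project_curve_coefficients(
            r.reduced_coefficients,
            r.reduced_covariance,
            per_country[r.country].var_spec,
            common,
            grid,
            from_center=0.0,
            to_center=0.0,
            grid_offset=ref_c,
        )
        ys.append(rc)
        covs.append(rcov)
    meta = pool_multivariate(np.array(ys), np.array(covs), method="reml")
    pc = pooled_curve(meta, common, grid, 0.0)
    return meta, pc, common


def run_study(
    births: pd.DataFrame,
    series_by_hospital: dict[str, TemperatureSeries],
    config: AnalysisConfig,
    out_dir=None,
    curves: bool = True,
) -> StudyResult:
    """Two-stage study: country-specific fits, then random-effects pooling
    of the contrast log-ORs and multivariate pooling of the cumulative
    curves.  Deterministic given inputs and config."""
    countries = sorted(set(births["country"].astype(str)))
    if len(countries) < 2:
        raise ValueError("run_study needs at least two countries; use run_country")

    if config.modifier is not None:
        base = replace(config, modifier=None)
        strata_results: dict[bool, StudyResult] = {}
        for flag in (True, False):
            sub = births.loc[births[config.modifier].astype(bool) == flag]
            strata_results[flag] = run_study(sub, series_by_hospital, base, curves=curves)
        top = run_study(births, series_by_hospital, base, out_dir=out_dir, curves=curves)
        top.config = config
        top.modifier_strata = strata_results
        return top

    per_country: dict[str, CountryResult] = {}
    notes: list[str] = []
    for c in countries:
        per_country[c] = run_country(births, series_by_hospital, config, country=c,
                                     curves=curves)
        for outcome, reason in per_country[c].skipped_outcomes.items():
            notes.append(f"{c}/{outcome}: skipped ({reason})")

    pooled: dict[str, PooledOutcome] = {}
    for outcome in config.outcomes:
        rs = [
            per_country[c].outcomes[outcome]
            for c in countries
            if outcome in per_country[c].outcomes
        ]
        if len(rs) < 2:
            notes.append(f"pooling skipped for {outcome}: <2 country estimates")
            continue
        meta = pool_univariate(
            [r.log_or for r in rs], [r.log_or_var for r in rs], method="dl"
        )
        mu = float(meta.pooled[0])
        se = float(np.sqrt(meta.pooled_covariance[0, 0]))
        po = PooledOutcome(
            meta=meta,
            odds_ratio=float(np.exp(mu)),
            ci_low=float(np.exp(mu - Z95 * se)),
            ci_high=float(np.exp(mu + Z95 * se)),
        )
        if curves:
            cm, pc, common = _pool_outcome_curves(rs, per_country, config)
            po.curve_meta, po.curve, po.common_var_spec = cm, pc, common
        pooled[outcome] = po

    result = StudyResult(
        per_country=per_country,
        pooled=pooled,
        config=config,
        seed=config.seed,
        warnings=notes,
    )
    if out_dir is not None:
        write_study_outputs(result, out_dir)
    return result


def forest_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for outcome in result.config.outcomes:
        countries = [
            c for c in sorted(result.per_country)
            if outcome in result.per_country[c].outcomes
        ]
        po = result.pooled.get(outcome)
        for i, c in enumerate(countries):
            r = result.per_country[c].outcomes[outcome]
            rows.append(
                {
                    "country": c,
                    "outcome": outcome,
                    "or": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "weight_percent": (
                        100.0 * float(po.meta.weights[i]) if po is not None else np.nan
                    ),
                    "Q": np.nan,
                    "Q_pvalue": np.nan,
                    "I2": np.nan,
                }
            )
        if po is not None:
            rows.append(
                {
                    "country": "POOLED",
                    "outcome": outcome,
                    "or": po.odds_ratio,
                    "ci_low": po.ci_low,
                    "ci_high": po.ci_high,
                    "weight_percent": 100.0,
                    "Q": po.meta.Q,
                    "Q_pvalue": po.meta.Q_pvalue,
                    "I2": po.meta.I2,
                }
            )
    return pd.DataFrame(rows)


def curve_frame(result: StudyResult) -> pd.DataFrame:
    """Country curves in absolute deg C; the pooled curve in deg C relative
    to the reference percentile (its centering scale)."""
    rows = []
    for outcome in result.config.outcomes:
        for c in sorted(result.per_country):
            r = result.per_country[c].outcomes.get(outcome)
            if r is None or r.curve is None:
                continue
            o, lo, hi = r.curve.odds_ratio()
            rows.append(
                pd.DataFrame(
                    {
                        "country": c,
                        "outcome": outcome,
                        "temp_c": r.curve.grid,
                        "or": o,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
            )
        po = result.pooled.get(outcome)
        if po is not None and po.curve is not None:
            o, lo, hi = po.curve.odds_ratio()
            rows.append(
                pd.DataFrame(
                    {
                        "country": "POOLED",
                        "outcome": outcome,
                        "temp_c": po.curve.grid,
                        "or": o,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["country", "outcome", "temp_c", "or", "ci_low", "ci_high"]
        )
    return pd.concat(rows, ignore_index=True)


def write_study_outputs(result: StudyResult, out_dir) -> None:
    """Forest table, curve grids and a run manifest as delimited/structured
    text with fixed float formatting (byte-identical on rerun)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    forest_frame(result).to_csv(
        os.path.join(out_dir, "forest.tsv"), sep="\t", index=False, float_format="%.6f"
    )
    curve_frame(result).to_csv(
        os.path.join(out_dir, "curves.tsv"), sep="\t", index=False, float_format="%.6f"
    )
    manifest = {
        "software": {"heatperi": result.version},
        "seed": result.seed,
        "config": result.config.to_dict(),
        "warnings": list(result.warnings),
        "exclusions": {
            c: {
                o: r.n_excluded_missing_exposure
                for o, r in result.per_country[c].outcomes.items()
            }
            for c in sorted(result.per_country)
        },
        "mmt": {
            c: {o: r.mmt for o, r in result.per_country[c].outcomes.items()}
            for c in sorted(result.per_country)
        },
    }
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def replicate_pooled_contrast(
    n_reps: int,
    seed: int,
    outcome: str = "perinatal_death",
    sim_overrides: dict | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Repeatedly simulate a four-country study and rerun the two-stage
    pipeline, collecting the pooled contrast OR and CI per replicate.

    Each replicate draws an independent seed stream from ``seed``; curves
    are skipped (only the percentile-contrast estimate is pooled).
    """
    from .synthetic_data import simulate_study

    config = config or AnalysisConfig(outcomes=(outcome,))
    sim_overrides = sim_overrides or {}
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rows = []
    for i in range(n_reps):
        births, series = simulate_study(seed=int(rep_seeds[i]), **sim_overrides)
        res = run_study(births, series, config, curves=False)
        po = res.pooled.get(outcome)
        if po is None:
            rows.append({"rep": i, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan})
        else:
            rows.append(
                {"rep": i, "or": po.odds_ratio, "ci_low": po.ci_low,
                 "ci_high": po.ci_high}
            )
    return pd.DataFrame(rows)


SENSITIVITY_KNOT_VARIANTS: dict[str, tuple[float, ...]] = {
    "knots_50": (0.50,),
    "knots_75": (0.75,),
    "knots_25_50": (0.25, 0.50),
    "knots_50_75": (0.50, 0.75),
    "knots_50_90": (0.50, 0.90),
    "knots_75_90": (0.75, 0.90),
    "knots_10_50_90": (0.10, 0.50, 0.90),
    "knots_25_50_75": (0.25, 0.50, 0.75),
}


def sensitivity_variants(base: AnalysisConfig) -> dict[str, AnalysisConfig]:
    """The robustness grid: hottest six months; shorter lag windows; knot
    placement variants; min/max temperature metrics; referral exclusion;
    50th-percentile reference; relative-humidity adjustment."""
    variants: dict[str, AnalysisConfig] = {
        "hottest6": replace(base, season_filter="hottest6"),
        "lag0": replace(base, lag_window=0),
        "lag0_1": replace(base, lag_window=1),
        "lag0_2": replace(base, lag_window=2),
        "metric_min": replace(base, metric="min"),
        "metric_max": replace(base, metric="max"),
        "exclude_referred": replace(base, referral_filter="exclude_referred"),
        "ref50": replace(base, contrast=(base.contrast[0], 0.50)),
        "humidity_adjust": replace(base, humidity_adjust=True),
    }
    for name, knots in SENSITIVITY_KNOT_VARIANTS.items():
        variants[name] = replace(base, var_knot_percentiles=knots)
    return variants


def sensitivity_suite(
    births: pd.DataFrame,
    series_by_hospital: dict[str, TemperatureSeries],
    base_config: AnalysisConfig,
    alt_series: dict[str, TemperatureSeries] | None = None,
) -> pd.DataFrame:
    """Run every sensitivity variant and collect pooled (variant, outcome,
    OR, CI) rows; individual variant failures are recorded, not fatal.
    ``alt_series`` (e.g. a coarser-resolution exposure product) adds an
    exposure-swap variant."""
    rows = []
    variants = sensitivity_variants(base_config)
    jobs = [(name, cfg, series_by_hospital) for name, cfg in variants.items()]
    if alt_series is not None:
        jobs.append(("alt_exposure", base_config, alt_series))
    for name, cfg, series in jobs:
        try:
            res = run_study(births, series, cfg, curves=False)
            for outcome in cfg.outcomes:
                po = res.pooled.get(outcome)
                if po is None:
                    rows.append(
                        {"variant": name, "outcome": outcome, "or": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "note": "pooling skipped"}
                    )
                else:
                    rows.append(
                        {"variant": name, "outcome": outcome, "or": po.odds_ratio,
                         "ci_low": po.ci_low, "ci_high": po.ci_high, "note": ""}
                    )
        except Exception as exc:  # noqa: BLE001 — suite must continue
            for outcome in cfg.outcomes:
                rows.append(
                    {"variant": name, "outcome": outcome, "or": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "note": f"failed: {exc}"}
                )
    return pd.DataFrame(rows)
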