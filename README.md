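# heatperi

Time-stratified case–crossover analysis of short-term heat exposure and
perinatal mortality.

Short-term heat episodes in the week before birth are a suspected trigger of
stillbirth and very early neonatal death, particularly in low-resource,
hot-climate settings. Estimating that association from hospital birth
registries is confounded by everything that varies between mothers and
seasons. `heatperi` implements the standard epidemiological answer — a
case–crossover design with time-stratified referents, distributed-lag
nonlinear exposure modelling, and two-stage meta-analytic pooling across
countries — as a tested, reusable Python package, together with a synthetic
multi-country registry generator with known injected effects so the whole
chain can be validated against ground truth.

## The model

For each perinatal death, the day of birth (case day) is compared with
every other day in the same calendar month sharing its weekday (3–4 control
days, all ≥ 7 days apart). Within such a stratum every slowly varying
confounder — maternal characteristics, season, weekday — is constant, so the
conditional likelihood identifies only the effect of short-term exposure
differences.

Exposure is the temperature history of the birth hospital over lags 0–6 d
(the last week of pregnancy). Its effect is modelled by a DLNM crossbasis:
a natural cubic spline over temperature (internal knots at the 10th, 75th
and 90th percentiles of the country's annual distribution) tensored with a
natural cubic spline over lag (knots equally spaced on the log-lag scale).
Each history `(T_0, …, T_6)` maps to one model row

    x = vec( Rᵀ C ),   R[k,·] = b_var(T_k),   C[k,·] = b_lag(k),

and the coefficients β maximize the stratified conditional-logistic
likelihood Σ [x_case·β − log Σ_j exp(x_j·β)] (Newton–Raphson, analytic
gradient and Hessian). The fitted coefficient matrix is collapsed over the
lag dimension to the cumulative exposure–response curve, summarized as

* the odds ratio comparing the 99th against the 75th temperature percentile
  (with Wald 95% CI),
* the full cumulative curve centred at the 75th percentile, and
* the minimum-mortality temperature (MMT), the curve's lowest point inside
  the 1st–99th percentile band.

Country estimates are pooled with DerSimonian–Laird random-effects
meta-analysis (Cochran's Q, I²); whole curves are pooled by multivariate
random-effects meta-regression (REML) after projection onto a shared spline
basis on the "°C above the reference percentile" scale.

## Worked example

```python
import heatperi as hp

# four synthetic countries, sixteen hospitals, known injected effect:
# true cumulative OR(99th vs 75th percentile) = 1.5
births, series = hp.simulate_study(seed=1, true_cumulative_or=1.5)

result = hp.run_study(births, series, hp.AnalysisConfig())
po = result.pooled["perinatal_death"]
print(f"pooled OR {po.odds_ratio:.3f} (95% CI {po.ci_low:.3f}-{po.ci_high:.3f}), "
      f"I2={po.meta.I2:.1f}%")
for country, cr in sorted(result.per_country.items()):
    r = cr.outcomes["perinatal_death"]
    print(f"{country:9s} OR {r.odds_ratio:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f}) "
          f"cases={r.n_cases} MMT={r.mmt:.1f} C")
```

prints

```
pooled OR 1.244 (95% CI 0.977-1.584), I2=0.0%
benin     OR 1.416 (0.941-2.131) cases=2145 MMT=27.7 C
malawi    OR 1.438 (0.841-2.458) cases=1289 MMT=15.7 C
tanzania  OR 0.616 (0.238-1.598) cases=522 MMT=21.3 C
uganda    OR 1.153 (0.782-1.702) cases=2110 MMT=23.1 C
```

Each country row is the first-stage estimate with its case count and
estimated MMT; the pooled row recovers the injected OR of 1.5 within
sampling noise for this single draw (averaged over 100 replicates the
pooled estimate is unbiased to within ~5% — see the acceptance script).
The same objects expose the full cumulative curves (`r.curve`, `po.curve`)
and fit diagnostics.

The command-line interface mirrors the library:

```
heatperi simulate --out-dir data --seed 1 --true-or 1.5
heatperi run --births data/births.csv --temps data/temperatures.csv --out-dir out
heatperi sensitivity --births data/births.csv --temps data/temperatures.csv --out-dir out
```

writing `forest.tsv`, `curves.tsv`, a run manifest, and the sensitivity
grid (hottest six months, lag windows 0/0–1/0–2, eight knot-placement
variants, min/max temperature metrics, referral exclusion, 50th-percentile
reference, humidity adjustment).

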