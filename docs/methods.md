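# Methods

This note documents the statistical machinery in `heatperi`, the choices
made where the design was genuinely open, and what the synthetic test bed
does and does not establish about real registry data.

## Study design

**Referent scheme.** The design is a time-stratified case–crossover: for a
perinatal death on day *d*, the control days are every other day in the
same calendar month *and year* sharing the weekday of *d* (3–4 controls,
separated from the case by multiples of 7 days). Matching within
month-and-year (rather than the same month across years) keeps referents
closely matched in time; the weekday match removes day-of-week effects and
the 7-day separation damps serial autocorrelation in exposure. Because
each stratum is one person compared with itself, all confounders constant
within a month — maternal age, parity, HIV status, facility — cancel in the
conditional likelihood. Cases whose hospital temperature series does not
cover the full lag window on every referent day are excluded and counted.

**Exposure.** Exposure is assigned from the birth hospital's daily series
(mean, min or max temperature, °C), as lags 0–6 (day of birth and the six
preceding days). Percentiles of the "annual temperature distribution" are
computed from all daily values of the chosen metric over the full study
period, pooled across the country's hospitals without weighting — one
country-wide distribution, the most stable interpretation. Quantiles use
linear interpolation of order statistics (h = (n−1)p + 1), and this
convention is fixed because percentile-contrast ORs depend on it. Relative
humidity derives from air and dew-point temperature via the Magnus formula
with α = 17.625, β = 243.04 °C; supersaturated inputs clamp to 100% with a
warning.

## Exposure–response model

**Crossbasis.** The temperature basis is a natural cubic regression spline
(piecewise cubic, C², linear beyond the boundary knots) with internal
knots at the 10th/75th/90th percentiles and boundary knots at the country
series minimum/maximum. The implementation constrains a cubic B-spline
basis to zero second derivative at the boundaries and continues it
linearly outside them; the test suite verifies span-equivalence against an
independent truncated-power construction. The lag basis is a natural
spline on [0, L] with internal knots equally spaced in log(lag) on (1, L)
and an intercept column, so a constant distributed-lag effect is
representable and the constant-history factorization `row = b_var(t) ⊗
colsum(C)` holds exactly. Short windows reduce the lag-knot count to L−1;
L = 0 collapses the lag dimension to a single constant column. Shorter
windows and alternative knot placements are configuration presets used by
the sensitivity grid.

**Fitting.** The conditional-logistic likelihood (one case per stratum) is
maximized by Newton–Raphson with analytic gradient and observed-information
Hessian; convergence at relative log-likelihood change < 1e−10 or score
max-norm < 1e−8, at most 100 iterations, step-halving on any decrease.
Columns are centred within stratum first (a pure reparameterization that
conditions out stratum effects and improves conditioning); columns that
are constant within every stratum, or exactly collinear after centring,
are detected by pivoted QR and dropped, and the coefficient vector is
re-expanded with zeros so the crossbasis layout survives. Strata with no
within-stratum variation are dropped and counted. |β| > 20 on any
coordinate triggers a separation warning. Variance is the inverse observed
information.

**Reduction and summaries.** With coefficient matrix Θ (var × lag) and
l = column sums of the lag basis over lags 0..L, the cumulative curve has
reduced coefficients Θl with covariance AΣAᵀ, A = I ⊗ lᵀ; the identity
"full-fit cumulative contrast = reduced-coefficient contrast" is asserted
to 1e−10 in tests. ORs between temperature percentiles are Wald intervals
on basis-difference contrasts. Curves are evaluated on a 0.1 °C grid over
the 1st–99th percentile range (center included exactly), and the MMT is
the grid minimizer within that band (ties → lowest temperature); the band
avoids boundary artifacts where the spline extrapolates linearly.

## Two-stage pooling

Scalar log-ORs pool by DerSimonian–Laird random effects (REML available),
with Cochran's Q, its χ² p-value (df = n−1) and I² = max(0, (Q−df)/Q)·100.
Curves pool by multivariate random effects y_i ~ N(μ, S_i + Ψ) with
unstructured Ψ estimated by REML through a Cholesky parameterization (so
Ψ is PSD by construction); if the optimizer fails, a moment estimate (PSD
projection of the sample covariance of the country vectors minus the mean
within-country covariance) is used with a warning. Countries have
different knot locations in °C, so before pooling each country's reduced
curve is re-expressed by least-squares projection onto a shared basis on
the *relative* scale — °C above the country's own reference percentile —
with knots at the pooled relative distribution's configured percentiles.
The projection is an exact linear map, so coefficients and covariances
transform consistently; the pooled curve is therefore centred at 0 °C
relative to the reference percentile, and the curve tables label that
scale explicitly.

## Synthetic data: what it emulates and what it does not

Temperature per hospital is an annual sinusoid plus stationary AR(1) noise
— the simplest process with realistic day-to-day autocorrelation, which is
what makes control-day exposures correlate with case-day exposures as in
real series. Min/max sit at ± the diurnal half-range around the mean, and
dew point sits a configurable depression below the mean. The four country
presets (Benin hot and stable, Malawi cool and seasonal, Tanzania and
Uganda intermediate) decompose each country's target birth-week
temperature s.d. into a seasonal amplitude plus an AR(1) marginal s.d.,
and their Poisson birth rates scale to the four registries' relative
sample sizes (about 26k/50k/24k/37k births over 2.5 years across four
hospitals each). `temp_annual_sd` is the AR(1) *marginal* s.d.; an
explicit `ar1_noise_sd` (innovation s.d.) overrides it.

Outcomes are Bernoulli with logit = logit(baseline) + f(w·T_week), where
w are lag weights (default uniform over lags 0–6) and f is by default
linear above the country-pooled 75th percentile with slope chosen so the
cumulative OR between the 99th and 75th percentiles equals a requested
value — making the estimand of the whole pipeline available in closed
form. A tabulated transfer function supports arbitrary shapes; the
U-shaped scenario uses f = c·(t − t_MMT)² with the true MMT at the 40th
percentile and default curvature 0.08 /°C², chosen so the injected effect
reaches OR ≈ 1.5–2 at the 99th percentile even in the least-variable
climate — comparable to reported heat effects and strong enough for the
curve's minimum to be statistically identifiable. Stillbirth/neonatal
decomposition (88% stillbirths among deaths; 56% antepartum among
stillbirths) and covariate prevalences are fixed draws independent of
exposure.

Deliberately not emulated: gestational-age dynamics, referral networks,
within-city exposure gradients, humidity–temperature dependence beyond a
noisy depression, and exposure-correlated covariates. Passing recovery
tests therefore demonstrates the *statistical chain* is correct and
calibrated under the stated generating process; it does not validate the
design against confounding structures the generator does not contain.

## Calibration experiments (problem sizes)

The replicate experiments run four countries per study: 200 null studies
at ~20,000 births per country for type-I calibration of the pooled CI, and
100 studies at ~50,000 births per country with injected cumulative
OR = 1.5 for bias and coverage. A single registry-scale run (~138,000
births) and one U-shape run complete the set; together they take about a
minute on one CPU. Null exclusion rates sit near 4% — slightly
conservative, as expected for DerSimonian–Laird with four homogeneous
studies, where estimated between-study variance widens the CI.

## Known limitations

* Wald/likelihood asymptotics throughout; no exact conditional inference
  or robust variances.
* DerSimonian–Laird with four countries is noisy in τ² and mildly
  conservative; REML is available but equally small-sample.
* The MMT is a grid argmin and inherits grid resolution (0.1 °C) and
  flat-curve instability.
* The common-basis projection for curve pooling is exact as a linear map
  but assumes curves are comparable on the relative-°C scale; °C-absolute
  alignment is available where climates are similar.
* The alternate-resolution exposure sensitivity is modelled as an input
  swap (a second temperature table), not as gridded-product ingestion.
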