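# Methods

## Model

`heatcast` forecasts temperature-related excess mortality at small-area
level by coupling three inputs: (i) area/age-specific exposure–response
functions between daily mean temperature and mortality, (ii) gridded
sub-daily temperature forecasts, and (iii) baseline populations and annual
mortality rates per area and age group.

For day *t*, age group *a* and area *j* the expected excess deaths are

    d_taj = (p_aj · m_aj / 365.25) · (1 − e^(−β_taj))

with `p_aj` the population, `m_aj` the baseline annual mortality rate
(their product divided by 365.25 gives the constant daily baseline
`b_aj`), and `β_taj` the cumulative log relative risk of the forecast
temperature on day *t*, read off the area/age-specific cumulative
exposure–response curve referenced at its minimum mortality temperature
(MMT). `1 − e^(−β)` is the attributable fraction (RR − 1)/RR with
RR = e^β; it is zero at the MMT, negative on the protective side of the
curve, and strictly below one for finite β, so the excess can never exceed
the baseline. Attribution follows the *forward* perspective: the lagged
risk caused by the exposure on day *t* is booked entirely to day *t*, which
makes day-labelled maps and multi-day totals additive without double
counting.

A note on the sign convention: with β defined as the cumulative log
relative risk (RR = e^β), the attributable fraction is 1 − e^(−β); writing
it 1 − e^β would require β to denote −log RR. This package uses the former
throughout, which is the convention under which AF = (RR−1)/RR holds.

## Risk-function estimation

Exposure–response functions are estimated with distributed lag non-linear
models (DLNMs). The cross-basis is the tensor product of

- an **exposure basis**: natural cubic spline of daily mean temperature,
  interior knots at the 10th/75th/90th percentiles of the calibration
  series, boundary knots at the observed range (a piecewise-linear
  "hockey-stick" basis is available as an alternative); and
- a **lag basis**: natural cubic spline *with intercept* over lags
  0–21 days, interior knots equally spaced on the log(1+lag) scale.

Each observation day's cross-basis row sums the products of the exposure
basis at the lagged temperatures and the lag basis at the lag, over the
full lag window; the first `max_lag` days of a series lack a complete lag
history and are excluded from fitting rather than padded. The natural
spline uses the closed-form truncated-power construction (linear beyond
the boundary knots); its span is identical to the QR-orthogonalised
variants used elsewhere, so fitted curves are unaffected by the choice of
parametrisation.

Daily death counts are regressed on an intercept plus the cross-basis
(plus optional confounder columns such as a long-term linear trend) in a
quasi-Poisson GLM with log link, fitted by iteratively reweighted least
squares (statsmodels). Overdispersion is estimated from the Pearson
chi-square and inflates the coefficient variance–covariance matrix, with a
floor at 1 so uncertainty is never deflated below the Poisson level.
Convergence requires a relative deviance change below 1e-8 within 50
iterations; rank-deficient designs and non-convergence raise typed errors.
Series with fewer than 10 events are fitted but flagged unstable, and a
region-level pooled function can be registered as a fallback — lookups
report when the fallback was used so outputs can flag it.

The fitted cross-basis coefficients are reduced to the *overall cumulative*
curve — the log-RR of sustained exposure at temperature *x* — by the linear
map that multiplies each exposure-basis coefficient block by the lag-basis
column sums; the reduced variance–covariance follows by the same map. The
MMT is the minimiser of this curve over a 0.1 °C grid between the 1st and
99th percentiles of the calibration temperatures (configurable); ties break
toward the lower temperature, and a flat curve returns the window midpoint
with a warning. The curve is then recentred at the MMT, making β zero
there by construction.

## Forecast ingestion and linkage

CF-style NetCDF forecasts are read through xarray; Kelvin is converted to
Celsius based on the variable's `units` attribute and a missing attribute
is an error — the scale is never guessed. Latitudes are reordered
ascending and longitudes normalised to [−180, 180). Sub-daily steps are
averaged to local-calendar-day means under a fixed configurable UTC offset
(no daylight-saving logic); days retaining fewer than a configurable
minimum of steps (default 4) are dropped with a warning. Each area is
linked to the grid at its population-weighted centroid, by nearest grid
node (default) or bilinear interpolation of the four surrounding nodes;
centroids outside the interior hull fall back to nearest with a warning,
and missing cells under nearest fall back to the closest non-missing
neighbour within one ring. Forecast temperatures outside a risk function's
calibration range are clamped to the range boundary and flagged — spline
extrapolation beyond calibration support is statistically unsafe.

## Monte Carlo uncertainty

Empirical confidence intervals (eCIs) are obtained by sampling coefficient
vectors from the multivariate normal sampling distribution of each risk
function (mean = reduced coefficients, covariance = reduced vcov, via the
symmetric eigendecomposition square root; eigenvalues below −1e-8 of the
largest raise an error rather than being silently repaired). β and the
excess are recomputed per cell per draw; the eCI of *any* aggregate is the
pair of empirical quantiles (linear, type-7 interpolation; level 0.95 by
default) of the per-draw sums over the aggregate's cells. Because draw *s*
is summed across all cells of an (area, age) unit, within-unit correlation
across days is preserved exactly; distinct units are sampled independently
(no cross-area covariance is available from per-area fits), which
understates total uncertainty, as does the exclusion of forecast
(meteorological) uncertainty. Zero covariance collapses the eCI onto the
point estimate exactly. Draw streams are spawned deterministically from a
single seed per run, in sorted (area, age) order, so results are exactly
reproducible and aggregate eCIs are identical whether computed before or
after aggregation.

Aggregation by any subset of {region, age group, date} sums the point
estimates (conserving the grand total to floating precision) and reports
excess rates per million with each distinct (area, age) population counted
once regardless of how many dates the group spans.

## Synthetic data generator

The generator defines the study conditions under which the package is
validated. Ground truth is a V-shaped cumulative log-RR in temperature
(vertex = true MMT, linear heat and cold arms) distributed over lags 0–21
with geometric weights (decay 0.6) normalised to sum to one — so the
cumulative log-RR of sustained exposure equals the V exactly, and expected
excess deaths have a closed form. Daily temperatures are a sinusoidal
seasonal cycle (mean 12 °C, amplitude 8 °C, peak mid-July) plus Gaussian
noise (sd 3 °C) and a small fixed per-area offset; deaths are Poisson with
mean `b · exp(Σ_l w_l · logRR(x_{t−l}))`. The default scenario uses 20
areas × 3 age groups × 3,650 days; per-area true MMTs are drawn uniformly
in 17–19 °C and heat/cold slopes in 0.02–0.04 / 0.005–0.015 per °C, scaled
by age factors 0.5/1.0/1.5. Populations and annual rates per age group
(60,000 / 25,000 / 8,000 and 0.003 / 0.030 / 0.120) emulate district-scale
units whose event counts permit stable per-series estimation; true
small-census-zone counts would require the multi-level pooling machinery
used to produce such risk functions in practice, which is out of scope
here (pre-estimated functions are ingested instead). Forecast grids are
written as CF-style NetCDF (0.4° default resolution, 8 sub-daily steps)
with the same seasonal cycle plus a configurable heatwave anomaly,
meridional gradient and diurnal cycle.

What the generator does **not** emulate: spatial correlation of weather
noise, forecast bias relative to the calibration temperature source,
harvesting dynamics beyond the 21-day window, seasonality of the baseline,
and covariates (humidity, pollution). Passing tests therefore demonstrate
the correctness of the estimation and attribution machinery under the
model's own assumptions, not robustness to violations of them.

## Numerical and design choices

- Smoothing bias at the vertex: the natural cubic spline rounds the
  V-kink of the synthetic truth, so when one arm of the curve is shallow
  the fitted minimum drifts a few °C into that arm. Because the curve is
  flat near its minimum this has little effect on attributed deaths, but
  recovered MMTs for low-count series should be read with that caveat;
  MMT recovery is correspondingly better for high-mortality series.
- CI coverage for the cumulative log-RR at MMT ± 5 °C is slightly below
  nominal (≈ 92% empirically at the default conditions) because intervals
  condition on the estimated MMT and the spline cannot represent the kink
  exactly; this matches standard practice, which also conditions on the
  estimated reference.
- Dispersion floor 1; deviance tolerance 1e-8; max 50 IRLS iterations.
- PSD checks tolerate a relative eigenvalue deficit of 1e-8; beyond that,
  errors are raised rather than repaired.
- Default Monte Carlo: 1,000 draws, 95% level, seeded; all stochastic
  outputs carry (n_sim, seed) metadata.
- Heat mode is the default for heatwave runs; cold and signed net modes
  exist, and net equals heat + cold by construction.
- Test and validation problem sizes (6–10 areas, 10-year series, 100
  recovery replicates) were chosen so the full suite runs in well under a
  minute while leaving parameter-recovery checks statistically sharp.

## Known limitations

Baseline mortality is constant within the year (a seasonality hook is
declared but unimplemented). Forecast bias calibration against the
risk-function temperature source, forecast-ensemble uncertainty, and
time-varying susceptibility are out of scope. The region-level fallback
for unstable areas is a pragmatic mechanism, not a reconstruction of the
multi-level pooling used in the estimation literature.
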