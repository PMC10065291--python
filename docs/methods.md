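# Methods

This note documents the models, algorithms and numerical choices behind
`heatlag`, the assumptions they rest on, and what the synthetic-data
experiments do and do not demonstrate.

## Study design

The design is a time-stratified case-crossover study: each death
contributes one matched set consisting of the death day (case) and the
other days of the same calendar month and year falling on the same weekday
(3–4 referents). Self-matching removes all time-invariant confounding (age,
sex, habits, residence); the time-stratified referent rule removes
confounding by weekday, season and long-term trend by design, and avoids
the overlap bias of symmetric referent schemes. Referent selection is
symmetric and localizable (a stratum is a deterministic function of the
calendar), so the conditional likelihood is valid. The remaining adjustment
set is daily absolute humidity and public holidays, which enter the model
explicitly.

Deaths whose case or referent day would need exposure from before the
exposure calendar's start (lag history incomplete) are excluded and
counted; deaths outside the hot season (November–March by default) are out
of the design's scope.

## Conditional logistic regression

With one case per stratum s and design rows x_j, the conditional likelihood
is `Π_s exp(x_case'β) / Σ_{j∈s} exp(x_j'β)` — the rare-event approximation
to the exact within-month death-day distribution, standard for daily
mortality hazards of order 10⁻³ or less. The fitter maximizes it by
Newton–Raphson with the analytic score and observed information, halving
the step whenever a full step would decrease the likelihood. Convergence:
max |score| < 1e-8 or a step shorter than 1e-10. The covariance is the
inverse observed information. Strata with no within-stratum variation in a
column contribute zero score for it and stay in the fit; a column constant
within every stratum has zero information and is dropped before fitting
(the pipeline does this and records it). A coefficient passing |β| > 15
(odds ratio beyond 3×10⁶) is treated as monotone likelihood and raised as a
separation error naming the column. Tests verify the fitter against a
brute-force enumeration optimizer (complex-step gradient, finite-difference
Hessian) to 1e-6 and against an established independent implementation.

## Distributed-lag cross-basis

The heat-wave indicator enters the model linearly in exposure and expanded
over lags 0..L by a lag basis B (rows = lags): the design row on day t is
`Σ_l HW[t−l]·B[l,·]`. The default lag basis is a natural cubic spline with
4 columns: boundary knots at lags 0 and L, two interior knots equally
spaced on the log-lag scale (`exp(i·log L/3)`, i = 1, 2 — lag 0 cannot be
logged, so the boundary stays on the natural scale), and the intercept
column included. **df convention:** with natural splines, 4 df = 2 interior
knots + 2 boundary-constrained columns only when the intercept is counted
in the basis; the implementation asserts this (tests check column count,
rank, and the exact knot positions). The basis uses the truncated-power
natural-spline construction, which is linear beyond the boundary knots with
zero second derivative there; any full-rank lag basis spanning the same
space yields the same cumulative odds ratio (verified to 1e-6 against the
identity basis).

Absolute humidity enters through the standard DLNM tensor: a natural cubic
predictor basis with 4 columns and *no intercept* (the stratum conditioning
absorbs it; an intercept column would be constant within strata and make
the information singular) — boundary knots at the observed range, interior
knots at equally spaced quantiles — crossed with a 4-df lag basis, giving
16 columns. The optional temperature adjustment (sensitivity variant) uses
the same construction. The quadratic B-spline lag-basis variant uses
`df − 3` log-spaced interior knots.

Effect summaries are linear contrasts: the cumulative log odds ratio is
`c'β_hw` with `c = Σ_l B[l,·]` (column sums), its variance `c'V̂c`, and the
95 % interval uses the fixed 1.96 normal quantile. Lag-specific odds ratios
use single basis rows with delta-method intervals.

## Weather preparation

Quality control keeps a station iff every calendar year has < 20 % missing
days and the whole period < 15 %. Hourly series are averaged to daily means
when at least 18 of 24 hourly values are present (an explicit package
default; any minimum can be configured). Imputation models the
cross-station daily vector as multivariate normal: station means are
natural-cubic-spline functions of time with 5 df per year (boundary knots
at the series ends, interior knots equally spaced), and the cross-station
covariance is free. EM alternates the conditional expectation of missing
entries given the day's observed entries (E) with an exact M-step — because
all stations share one time design, the GLS coefficient update collapses to
per-station OLS, and the covariance update includes the conditional
covariance of the imputed entries — so the observed-data log-likelihood is
non-decreasing (asserted per iteration in tests). Convergence is declared
when no imputed value moves by more than 1e-4; observed entries are never
altered; a singular covariance is ridge-regularized by 1e-8·trace/n on the
diagonal. Temperature and relative humidity are imputed as separate
systems, and absolute humidity is derived afterwards.

## Exposure estimation

Distances are planar kilometres (synthetic coordinates are generated in km;
geographic inputs can be projected equirectangularly about the domain
centroid — sub-metre error at city scale). IDW prediction is the convex
combination `Σ d_i^{-p} z_i / Σ d_i^{-p}` over the k nearest in-radius
stations, with an exact short-circuit for targets within 1e-9 km of a
station. LOOCV predicts each station-day from the remaining stations for
every combination of power p ∈ {1, 1.5, 2, 2.5, 3}, k = 1..n_stations and
search radius (default unbounded), and selects the minimum-RMSE
combination; ties break toward smaller p, then smaller k; a combination
with no valid prediction scores infinite RMSE. The gridded mode evaluates
the interpolator at 1 km cell centers and averages the cells whose centers
fall within a 1 km buffer of the residence (cell-center membership; an
empty buffer falls back to point IDW and is logged). Both modes reduce to a
fixed subjects-by-stations linear map, so daily fields are matrix products.

Absolute humidity uses the Magnus saturation-vapor-pressure form with
constants 6.112 hPa / 17.62 / 243.12 °C:
`AH = 216.7·(RH/100·6.112·exp(17.62T/(243.12+T)))/(273.15+T)` g/m³, valid
for T ∈ [−20, 60] °C and monotone in both arguments there.

### Validating LOOCV parameter recovery

Leave-one-out selection can only recover a "generating" parameter set if
the data are self-consistent under the leave-one-out predictor — a field
interpolated from a *separate* network is not, and the power is then only
weakly identified (empirically, selections barely track the generating
power). The package therefore provides an exact construction
(`generate_idw_selfconsistent_field`): three source locations carry twin
stations (identical coordinates and values, so the coincidence rule makes
their held-out predictions exact under every candidate), and the interior
stations solve the linear fixed-point system v = Wv of the leave-one-out
IDW operator at the generating (p, k). Held-out errors are then zero at the
generating combination up to 1e-6 noise, and LOOCV recovers it exactly; the
constructor rejects sampled geometries that disconnect the interior from
the sources or that cannot discriminate neighbouring powers (the caller
retries with another seed).

## Heat-wave definition

Per-subject thresholds are empirical quantiles (linear interpolation at
rank 1+(n−1)p) of the subject's hot-season daily mean temperatures pooled
over all study years; at least 30 hot-season days are required. A heat-wave
day strictly exceeds the threshold (strictness is a declared convention)
and belongs to a run of ≥ 2 consecutive exceedance days. Runs are evaluated
on the continuous daily calendar with off-season days masked out, so a run
never bridges the off-season boundary; within the hot season runs cross
month boundaries freely. Flag counts are non-increasing in the percentile
and detection is idempotent (both tested).

## Synthetic world

The generator emulates a tropical southern-hemisphere city:

* **Stations** — 13 by default, uniform over a 40 km square.
* **Weather** — daily mean = 24 °C + 3.8 °C·cos(2π(doy−15)/365.25)
  (summer peak mid-January, matching a November–March hot season; the
  hot-season mean lands near 27.5 °C with sd ≈ 2.5 °C), plus an anomaly
  field that is AR(1) in time (ρ = 0.7) with spatially correlated
  innovations (exponential covariance, range 20 km, sd 2 °C, simulated by
  Cholesky factorization over the station set — exact at this size).
  Relative humidity has the same anomaly structure around 70.9 % (sd
  9.7 %), clipped to [5, 100]; it carries no seasonal cycle of its own.
  Missingness is completely at random (default 5 %).
* **Cohort** — 6,000 subjects, uniform coordinates, sex Bernoulli(0.5),
  70 % aged 65+.
* **Deaths** — daily probability `b·exp(θ·Σ_l w_l·HW[t−l])` on hot-season
  days with b = 9×10⁻⁴, at most one death per subject (per-day Bernoulli
  scan in date order — exact first-event semantics), cause cardiovascular
  with probability 0.69. The at-risk calendar is the hot season: the design
  analyzes only hot-season deaths, and restricting risk to those days lets
  a 6,000-subject cohort yield ≈ 3,000 analyzable deaths over five years
  without extreme depletion. Lag weights default to normalized exp(−l/2)
  over lags 0..5 — a smooth, acute-dominant decay consistent with
  short-term mortality displacement — and the injected cumulative log odds
  ratio θ defaults to log 1.3. The generator refuses configurations whose
  per-day hazard reaches 1.

What the synthetic world does **not** emulate: urban heat-island structure,
altitude/land-cover gradients, subject mobility, within-day exposure
variation, frailty heterogeneity, or humidity effects on mortality (the
injected hazard depends on the heat-wave indicator only). Passing recovery
tests therefore demonstrate that the estimator chain is consistent and
calibrated under the stated model, not that these real-data complications
are handled.

## Monte-Carlo experiments

Recovery replicates simulate gap-free weather and point-mode IDW with power
2 over all stations (the imputation and gridding stages are exercised by
their own tests; keeping them out of the replicates isolates the estimator
and keeps 100 replicates within minutes on one core). Each replicate fits
the full model — heat-wave cross-basis (ns, 4 df), humidity tensor (16
columns), holiday dummy — on ≈ 2,900–3,000 pooled deaths and records the
cumulative OR and its 95 % interval. At θ = log 1.3 the median estimate
sits in [1.20, 1.40]; at θ = 0 the CI-excludes-1 rate sits near 0.05.
Interval coverage of the truth is close to, but can run a few points below,
the nominal 0.95 at this study size: all matched sets share one city-wide
weather realization, and the conditional maximum-likelihood estimate
carries a small weather-dependent finite-sample attenuation that the
model-based (inverse-information) variance cannot see. The attenuation
vanishes as the cohort grows (with four times the deaths on the same
weather, the conditional mean matches the injected log OR to three
decimals), and within a fixed weather realization the reported standard
errors match the empirical spread. Holidays are a synthetic calendar of 12
random dates per year.

## Numerical conventions and degenerate inputs

* Quantiles: numpy's linear interpolation (rank 1+(n−1)p) throughout.
* IDW ties in LOOCV break toward smaller power, then fewer neighbors.
* The 1.96 multiplier is fixed for 95 % Wald intervals on the log scale.
* Empty populations, zero hazards, all-missing stations, all-dropped
  strata, and separation all raise explicit errors (or return empty
  outputs where the contract says so); failed analysis cells are marked in
  the results table without aborting the run — extreme definitions (99th
  percentile) legitimately produce unstable cells.
* End-to-end determinism: all randomness flows through
  `numpy.random.default_rng` seeded from the configuration; identical
  configuration and seed give byte-identical outputs.

## Known limitations

Kriging or covariate-aware interpolation is deliberately out of scope; the
Wald intervals ignore threshold-estimation uncertainty (thresholds are
treated as fixed subject attributes, as in the design being implemented);
the EM imputation assumes joint normality of station anomalies and MCAR
missingness; duration thresholds other than ≥ 2 days and heat-wave metrics
other than daily mean temperature are not implemented.
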