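# Methods

This document records the statistical model, the definitions of every derived
quantity, the synthetic-data generators, and the numerical and design choices
made in `springpulse`.

## 1. Study setting and data model

Two mule deer herds — `NAR` (northern) and `SAR` (southern) — carry GPS
collars; each collared animal contributes a migration interval (start and end
date, net displacement in km) per spring. Daily environmental inputs are
streamflow at one or more gages (m³/s) and basin-mean air temperature (°C).
All within-year timing is expressed as Julian day (1 = Jan 1; leap years have
366 days).

### Input formats

- Daily values: plain CSV (`station_id,variable,units,date,value`) or USGS RDB
  (tab-separated, `#` comments, a column-name row and a column-format row such
  as `5s 15s 20d 14n 10s`). The RDB reader takes the `00060` discharge column
  when present, otherwise the first numeric (`n`-format) non-`_cd` column, and
  maps provisional codes (`Ice`, `Eqp`, …) to missing. Duplicate or
  out-of-order dates are integrity errors reported with line numbers.
- Migration tables: CSV with
  `herd,year,animal_id,start_date,end_date,displacement_km`.

## 2. Derived quantities

### Spring-pulse day (hydrology)

For a complete year of daily flows `Q_1..Q_N` and a reference level `Q̄`, the
cumulative departure is `S_j = Σ_{k≤j} (Q_k − Q̄)`. The **spring-pulse day**
is the `j` minimizing `S_j` (earliest day on ties) — the day before sustained
snowmelt flow exceeds the mean. Two conventions are supported: `min` (the
argmin itself, the default) and `min_plus_one`. The reference level is the
current year's mean (`Dsm` family) or the previous year's mean (`Dpsm`,
"lagged" family). Gaps up to `gap_days` (default 7) are linearly
interpolated; longer gaps make the year incomplete and it is rejected.

### Temperature phenology

- Base temperature: `T_base = −0.25·latitude + 13` (°C); at latitude 41°N,
  `T_base = 2.75 °C`.
- Daily growing-degree units: `max(0, T_mean − T_base)` (the floor is
  optional).
- **GDD-180 day**: first day the cumulative GDU sum strictly exceeds 180.
- **Jerk day**: a three-parameter logistic
  `f(t) = Asym / (1 + exp((xmid − t)/scal))` is fit to cumulative GDU
  (`scipy.optimize.curve_fit`, self-started with `Asym₀ = 1.05·max`, `xmid₀`
  at the half-maximum crossing, `scal₀ =` (10%→90% span)/4). The third
  derivative of `f` has two equal global maxima at
  `p = f/Asym = 1/2 ∓ √6/6`; the **earlier** one marks the onset of spring
  warming acceleration:

  `jerk_day = xmid + scal · log((1/2 − √6/6)/(1/2 + √6/6)) ≈ xmid − 2.2924·scal.`

### Daily covariates

For herd-year `i` and Julian day `J`: `Dsm = J − pulse_day_i`,
`Dpsm = J − lagged_pulse_day_i`, `JERK = J − jerk_day_i`,
`GDD = J − gdd180_day_i`, plus raw daily `T_mean` and a herd dummy
(`NAR = 0`, `SAR = 1`). Candidate covariate pairs with Pearson `|R| > 0.20`
are flagged by the collinearity screen before model fitting.

### Migration response

Within a herd-year, the **simultaneous count** on day `d` is the number of
animals whose (inclusive) migration interval covers `d`. The **group
initiation day** is the first day the count reaches its maximum. The
**binary response** for the logistic model is `y_{id} = 1(d ≥ initiation_i)`
over days 1..150 (the first-151-days horizon); an initiation past the horizon
produces an all-zero response with a warning.

## 3. Bayesian logistic regression

Daily responses are modeled as `y ~ Bernoulli(θ)`,
`logit(θ) = Xβ`, with independent diffuse priors `β_k ~ N(0, sd = 100)`
(precision 10⁻⁴).

Sampling is random-walk Metropolis, vectorized across 3 chains:

- The posterior mode is found by L-BFGS-B; the proposal covariance is the
  inverse of the analytic negative Hessian there (Laplace approximation),
  scaled by `2.4/√k` (`k` = number of coefficients).
- Chains start overdispersed around the mode. Defaults are 20 000 steps with
  1 000 burn-in; tests and the acceptance script use 3 000–5 000 steps, which
  the Laplace proposal makes sufficient (acceptance rates ≈ 0.3–0.5,
  `R̂ < 1.01`).
- Convergence: Gelman–Rubin `R̂` per coefficient (between/within-chain
  variance ratio, implemented directly and cross-checked against
  `arviz.rhat` in the test suite); `converged` requires all `R̂ < 1.1`.
- Complete separation (single-class response) is detected before sampling and
  raised as an error.

### Scores and prediction

- **DIC** `= 2·D̄ − D(β̂)` where `D(β) = −2·log-likelihood`, `D̄` is the
  posterior-mean deviance and `β̂` the posterior-mean coefficient vector.
- **Recall / precision** at the posterior-median probability with threshold
  `θ > 0.5`; either is NaN when its denominator is empty (DIC is always
  defined).
- **Predicted initiation day** for a herd-year: the first day whose
  posterior-median `θ` exceeds 0.5; `RMSE` compares predictions to observed
  (or, in synthetic mode, true) initiation days. Period summaries report the
  median and IQR of per-period predicted days over configurable year ranges
  (defaults 1943–1959, 1960–1979, 1980–1999, 2000–2018).

Models are ranked by precision (descending), then recall, then DIC
(ascending); NaN precision ranks last.

## 4. Trend analysis

- **Kendall–Theil (Theil–Sen)**: slope = median of all pairwise slopes,
  intercept = median of `y_i − slope·x_i` (`scipy.stats.theilslopes`,
  `method="joint"`); a brute-force O(n²) oracle is kept in the package for
  verification.
- **Mann–Kendall**: `S = Σ_{i<j} sign(y_j − y_i)` with tie-corrected variance
  `[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18` and a continuity correction for the
  normal approximation; requires `n ≥ 4`.
- A lag-1 autocorrelation check flags series with `|r₁| > 1.96/√n`, where the
  MK p-value is anti-conservative.

## 5. Synthetic generators

All generators are driven by `numpy.random.SeedSequence([seed, year, tag])`,
so every series is individually reproducible and independent.

- **Temperature**: `T(j) = mean + amplitude·sin(2π(j − phase)/365) + ε`,
  defaults mean 4.5 °C, amplitude 12 °C, phase day 106, noise sd 2 °C — a
  mid-latitude mountain-basin annual cycle.
- **Hydrograph**: baseflow 2 m³/s; at the prescribed onset day the flow
  rises linearly over `rise_days = 5` days to baseflow + 20 m³/s, then
  recedes exponentially at 0.05/day; multiplicative lognormal noise
  (fraction 0.05). The sharp rise and slow recession mimic a snowmelt
  freshet; with these defaults the cumulative-departure detector recovers
  the true onset within `[onset − 2, onset]` at noise fractions up to 0.10.
- **Migration responses**: given true coefficients `β` (default
  `(0, 0.25, −0.25)` on intercept/`Dsm`/herd) and the daily covariates,
  either i.i.d. Bernoulli draws per day (`bernoulli_iid`) or a single
  geometric-style first-success draw that yields a monotone step
  (`first_success_step`). Ground-truth initiation days are returned with
  the records.
- **Trend series**: linear trend plus Gaussian noise, for calibrating the
  trend tests (e.g. the Mann–Kendall type-I error is ≈ 3–5% at nominal 5%).
- **`records_from_summary`** engineers per-animal migration intervals from a
  herd-year summary row so that `n`, earliest individual start, group
  initiation day, maximum simultaneous count and median displacement are all
  reproduced exactly; this turns the packaged 18-row herd-year table back
  into record-level input for the full chain.

Limits: generated years are independent (no flow persistence between years),
temperature and flow are generated independently of each other, and the
response generators condition only on the covariates supplied — they are
verification scaffolding, not ecological simulators.

## 6. Numerical choices

- **Jerk-day oracle**: verifying the closed form numerically with triple
  finite differences of `f` in raw day units loses ~2 decimal digits to
  cancellation. The numeric maximizer therefore works on the scale-free
  variable `τ = (t − xmid)/scal` with step 0.001, evaluates `f` in extended
  precision, takes third differences centered at `τ_i + 1.5·step`, picks the
  earliest of the two near-equal lobes, and refines with a parabola vertex.
  Worst-case disagreement with the closed form is < 0.004 days over
  `scal ∈ [2, 30]`.
- **DIC**: the posterior-mean deviance is averaged over ≤ ~1000 evenly-spaced
  posterior draws (exact when fewer draws exist); the posterior-median `θ`
  is computed in row chunks over ≤ 4000 thinned draws to bound memory.
- Ties in argmin/argmax (pulse day, group initiation, jerk lobes) always
  resolve to the earliest index.
- All derived seeds stay below 2³¹ for portability.

## 7. Acceptance report

`python scripts/acceptance.py --seed <int> --out <path>` recomputes, from
scratch and offline:

1. the four cross-herd statistics from the packaged herd-year table
   (median group-initiation difference 1 day, median displacement difference
   20 km, latest group initiation day 137, earliest southern individual
   day 20);
2. maximum disagreement between Theil–Sen / pulse-day / jerk-day and their
   brute-force oracles;
3. 95% credible-interval coverage of known logistic coefficients over 20
   replicates (n = 3000 rows each) and the worst `R̂`;
4. end-to-end synthetic RMSE and the DIC ranking of the true-covariate model
   against a temperature-only competitor;
5. the empirical Mann–Kendall type-I error over 200 null series.

Each JSON entry is `{"value": ..., "n": ...}` with `n` the underlying sample
size. The report is deterministic given `--seed`.
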