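# Methods

This note documents the statistical procedures implemented in `speiyield`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## SPEI computation

**Potential evapotranspiration.** PET uses the classical Thornthwaite
temperature/daylength formulation. The annual heat index is
`I = Σ_m (T̄_m/5)^1.514` over the twelve per-calendar-month mean
temperatures of the input record (months with non-positive means
contribute nothing), and the exponent is the standard cubic polynomial in
`I`. Unadjusted PET is `16 (10T/I)^a` for `0 < T < 26.5 °C`, zero at or
below freezing, and the high-temperature polynomial
`−415.85 + 32.24T − 0.43T²` at or above 26.5 °C. The correction factor is
`(N/12)(NDM/30)` with daylength `N` computed from the solar declination at
the month's mid-day (`δ = 0.4093 sin(2πJ/365 − 1.405)`,
`ω_s = arccos(−tanφ tanδ)`, `N = 24ω_s/π`) and `NDM` the calendar days in
the month (non-leap). This matches the formulation used by the standard
SPEI calculators. Monthly temperature and latitude are the only inputs;
this is a coarse PET model, adequate for a standardized anomaly index but
not for absolute water-budget work.

**Water balance and aggregation.** `D_i = P_i − PET_i` per month; the
`k`-month series is the trailing window sum `Σ_{j=m−k+1}^m D_j`, undefined
for the first `k − 1` months of a record.

**Distribution fitting.** Each calendar month's aggregated values are
fitted separately with a three-parameter log-logistic distribution,
`F(x) = [1 + (α/(x−γ))^β]^{−1}`, by probability-weighted moments. With
`a_s = E[X(1−F)^s]`, the sample L-moments are `λ₁ = a₀`, `λ₂ = a₀ − 2a₁`,
`λ₃ = a₀ − 6a₁ + 6a₂`, and

```
β = λ₂/λ₃,   α = λ₂ β / (Γ(1+1/β)Γ(1−1/β)),   γ = λ₁ − α Γ(1+1/β)Γ(1−1/β).
```

Two PWM estimators are available: the exact unbiased combinatorial
weights (default) and the plotting-position weights `F_i = (i − 0.35)/n`
used by some legacy calculators; the choice is a keyword
(`pwm_method`). The calibration period defaults to the full input record;
a `(start, end)` year window may be supplied instead, in which case
parameters are fitted on the window and applied to the whole record.

*Left-skewed samples.* The log-logistic above requires positive sample
L-skewness (`λ₃ > 0`). In finite records (36 values per calendar month) a
few site-months can come out slightly left-skewed even when the underlying
process is right-skewed. Rather than fail, the fit covers the full
generalized-logistic family: for `λ₃ < 0` the same algebraic expressions
produce `β < 0, α < 0`, which is the mirror-image (left-skewed) member with
support below the origin and a valid, monotone CDF. This is the same
family reference SPEI implementations fit. Right-skewed samples — the
overwhelming majority — still yield the conventional `α > 0, β > 1`
parameters.

**Standardization.** The exceedance probability `P = 1 − F(x)` maps to the
index through the Abramowitz–Stegun rational approximation of the normal
quantile with the constants C₀ = 2.515517, C₁ = 0.802853, C₂ = 0.010328,
d₁ = 1.432788, d₂ = 0.189269, d₃ = 0.001308; for `P > 0.5` the formula is
applied to `1 − P` and the sign flipped. Its documented maximum absolute
error against the exact quantile is 4.5e-4, verified in the tests against
`scipy.stats.norm` as an independent oracle. When an aggregated value
falls at or below the fitted origin (or beyond the upper support of the
mirrored branch) the probability is clamped to `[1e-6, 1 − 1e-6]`, which
only affects values already deeper than |SPEI| ≈ 4.75.

**Classification.** Moisture levels partition the axis with half-open
intervals closed on the drought side: ≤ −2 extreme drought, (−2, −1]
moderate drought, (−1, −0.5] slight drought, (−0.5, 0.5) normal, [0.5, 1)
slight wetting, [1, 2) moderate wetting, ≥ 2 extreme wetting. Published
level tables sometimes print touching decimal ranges (−0.99 ~ −0.5 etc.);
the half-open convention is the one consistent with the quantitative
response table this package produces.

## Trend tests

Mann-Kendall S with the tie-corrected variance
`Var(S) = [n(n−1)(2n+5) − Σ e_i(e_i−1)(2e_i+5)]/18` (`e_i` = extent of each
tied value group), continuity-corrected `Z`, and two-sided p-values.
Sen's slope is the median of all pairwise slopes. Only value ties occur
(one observation per time step), so no time-tie correction is needed.
Series of length 4–10 are allowed but flagged (`small_sample`) and warned
about, since the normal approximation is only asserted for n > 10; shorter
series are rejected. No pre-whitening is applied — the tests are used here
on annual aggregates where serial correlation is mild; results on strongly
autocorrelated series should be interpreted accordingly.

## Yield–moisture linkage

Growth stages follow the winter-wheat calendar: S1 Oct–Nov (sowing and
seedling), S2 Dec–Feb (over-wintering), S3 Apr–Jun (late growth); March
deliberately belongs to no stage, and the full season spans the nine
months Oct–Jun. A season is labelled by its harvest year, so Oct–Dec carry
a −1 year offset. A stage covariate at scale `k` is the arithmetic mean of
the `k`-month SPEI values of the stage's months (e.g. SPEI_3_S3 = mean of
the 3-month SPEI of April, May and June).

Yields and covariates are both detrended by first-order differencing —
this removes the technology trend in yields and any slow drift in the
index, and makes the correlation invariant to adding linear trends to
either series. Pearson r with the two-sided t-test (n − 2 df) and star
annotations at 5 % (*) and 1 % (**) complete the tables. At least five
overlapping consecutive seasons are required per site.

## Panel model

`Y_it = β_i + α₁ s_it + α₂ s_it² + α₃ t + u_it` is estimated by LSDV: site
dummies (no global intercept), the covariate, its square, and a time index
`t = 1…T` over the panel's year range. Identification notes: only
differences of `t` matter for the slope, and the reported mean intercept
is the unweighted average of the site intercepts; site effects are also
reported as deviations from that mean (they sum to zero).

**Serial correlation.** A Durbin-Watson statistic is computed from the
OLS residuals with first differences taken within sites only (a pooled DW
across concatenated sites would create spurious cross-site differences).
Under the `auto` policy, AR(1) errors are assumed when DW leaves
[1.5, 2.5] (configurable); policies `on`/`off` force either branch. The
AR(1) fit is iterated Cochrane-Orcutt: ρ is estimated from the pooled
within-site regression of residuals on their lags, all regressors
(including the dummies) are quasi-differenced within sites with the first
observation per site dropped, the model is refit, and the cycle repeats to
|Δρ| < 1e-6 (max 50 iterations). This is the textbook estimator; software
that estimates the AR term by nonlinear least squares will differ slightly
in finite samples. The reported DW always refers to the pre-AR(1)
residuals, the adjusted R² to the final (transformed, when AR(1) is
applied) regression.

**Derived response surface.** All responses are reported in kg/ha relative
to neutral moisture: `response(s) = 1000 (α₁s + α₂s²)`. For a concave fit
(α₂ < 0) the optimum is the vertex `−α₁/(2α₂)` and the loss thresholds are
the roots `{0, −α₁/α₂}`; between them the response is a gain, outside a
loss. The per-level response table evaluates the response at each moisture
level's interval endpoints; when the vertex falls strictly inside an
interval the upper bound is the (attained) vertex response. Note this
vertex-aware bound can exceed the endpoint value — for the slight-drought
interval (−1, −0.5] with a vertex near −0.6 the true maximum sits at the
vertex, not at −0.5. Reporting precision: responses to 1 decimal kg/ha,
derived thresholds to 2 decimals.

## Synthetic data

The generator emulates a ten-station network spanning 31–35 °N with mean
annual temperature rising from 13 °C (north) to 16 °C (south), annual
precipitation from 724 mm (north) to 1210 mm (south), and warming slopes
from 0.04 to 0.07 °C/yr (strongest in the south). Temperature is
`site mean + A·cos(2π(month−7)/12) + slope·(year−start) + N(0, σ)` with a
July peak, amplitude 12.5 °C and σ = 0.8 °C — values typical of the humid
East-Asian monsoon margin. Monthly precipitation is gamma-distributed
(shape 4, i.e. CV = 0.5) around a fixed climatological weight vector
(18 % of the annual total in July, 3 % in December) scaled to the site
total. Yields come from the panel model itself with intercepts around
3.34 t/ha, slopes (−0.1592, −0.1297, 0.0626), ρ = 0.39 and a residual
σ of 0.25 t/ha; the AR(1) error starts from its stationary distribution
and is independent across sites. The residual σ is a synthetic choice (no
empirical estimate exists for it), picked so that moisture explains a
realistic minority share of detrended yield variance.

One `numpy` generator seeded once drives all draws, so panels are
bit-reproducible. The generator deliberately omits: spatial correlation
between stations, daily weather and extreme events, leap days, multi-year
precipitation cycles, and any yield response outside the quadratic model.
Consequently, passing tests demonstrate internal consistency of the
estimators under the model's own assumptions — not that the model is
adequate for any particular real region.

## Problem sizes used in the test suite

Deterministic checks run on 3-site, 36-year panels; the calibration and
parameter-recovery checks use the full 10-site, 36-year configuration with
35 harvest years and 200 Monte-Carlo replicates; the trend-test size check
uses 10 000 null replicates at n = 36. These sizes give Monte-Carlo
standard errors comfortably below the asserted tolerances (e.g. the mean
of 200 slope estimates has an se ≈ 0.001 t/ha against a ±0.02 band).

## Known limitations

- Thornthwaite PET underestimates atmospheric demand in windy/arid
  climates; the package intentionally offers no Penman-Monteith option.
- The log-logistic fit needs ≥ 10 values per calendar month; short records
  should use a longer calibration window, not fewer months.
- The panel estimator assumes strictly exogenous covariates; yields that
  feed back into moisture (irrigation from reservoirs, say) violate it.
- Standard errors and confidence intervals for the derived quantities
  (optimum, thresholds) are not computed.
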