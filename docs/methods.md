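# Methods

## Model

For district *c* with weekly severe-diarrhoea counts `D_t` the first-stage
model is an overdispersed log-linear count regression

```
ln E[D_t] = α + cb(temp_t) + ns(dewp_t; 3 df) + ns(t; 3 df/year) + β·holiday_t
```

estimated by iteratively reweighted least squares on the Poisson score
equations; the quasi-Poisson dispersion φ = Pearson χ²/(n−p) multiplies the
inverse Fisher information to give the coefficient covariance. "Quasi-Poisson"
refers to the variance function Var = φ·μ, not to the link, which is the log
link throughout. No offset is used: the outcome is a count, not a rate.

`cb(temp)` is the DLNM cross-basis. Its entry for week *t* and column
*(j,k)* is `Σ_{l=0..L} R_j(temp_{t−l}) C_k(l)`: `R` is a natural cubic
spline of temperature without intercept (2 internal knots → 3 columns) and
`C` a natural cubic spline of the integer lags `0..L` with intercept (3
internal knots → 5 columns), giving 15 columns at the default `L = 4`.
Because the data are weekly the lag axis is a finite sum, not an integral.
Coefficients are stored exposure-major (`index = j·vl + k`); the reductions
and stage two rely on that layout.

Reduction to the overall cumulative curve is linear:
`η_j = Σ_k θ_{jk} M_k` with `M_k = Σ_l C_k(l)`, and `Σ = A V Aᵀ` for the
matching map `A = I ⊗ M`. Lag-specific summaries use
`log RR(x, l) = (R(x) − R(ref))ᵀ Θ C(l)`; by linearity the lag-specific log
RRs sum exactly to the cumulative log RR, which the tests exploit as an
internal identity.

Stage two pools district `(η_i, Σ_i)` under `η_i ~ N(μ, Σ_i + Ψ)`.
Ψ is estimated by REML (default; ML and fixed-effects available), with Ψ
parameterised through its Cholesky factor so positive semi-definiteness is
structural; the optimiser is a Nelder–Mead pass refined by BFGS, started at
a method-of-moments Ψ (which is also the fallback if optimisation fails,
with a warning). Cochran Q uses fixed-effects weights — the conventional
definition — with df = (k−1)·dim, and I² = max(0, (Q − df)/Q)·100; the
multivariate I² definition varies across software and this form is the one
implemented, not asserted to coincide with any other package's. BLUPs are
`μ + Ψ(Σ_i + Ψ)⁻¹(η_i − μ)` with conditional covariance
`Ψ − GΨ + (I−G) V_μ (I−G)ᵀ`, `G = Ψ(Σ_i + Ψ)⁻¹`.

## Curve summaries

The minimum-risk temperature (MRT) is the minimiser of the uncentred
cumulative curve on a 0.01 °C grid between the 1st and 99th percentiles of
the observed temperatures (ties break toward the lower temperature; a
strictly monotone curve therefore returns a trimming bound). The search
grid is finer than the 0.1 °C at which MRTs are conventionally reported, to
avoid resolution artifacts. Relative risks at the 5th/95th percentile
temperatures versus the MRT carry Wald 95% intervals with z = 1.959964.
Percentiles use the linear-interpolation empirical definition throughout
and are computed on all weeks in the study window (not post-lag-trimming).
Recentering is a pure shift of the log curve, so RR ratios between any two
temperatures are reference-invariant.

## Design choices

- **Week convention.** Weeks are consecutive 7-day blocks anchored at the
  study window start; a partial terminal week is dropped. This is
  reproducible from the window alone and avoids any calendar-week
  convention ambiguity.
- **Severity classification** reads structured boolean flags
  (dehydration/co-morbidity); a keyword front-end (`flags_from_text`) can
  derive flags from free-text diagnoses but the core stays deterministic.
  Deaths with A00–A09 codes are severe by definition; other ICD chapters
  are excluded outright.
- **Weather imputation** regresses the gapped station on the other
  stations' same-day values plus annual sin/cos harmonics, fitted on
  complete days by OLS; observed values are never touched, and a station
  missing more than 5% (configurable) is refused — heavily gapped variables
  (such as rainfall in the motivating setting) should be dropped, not
  imputed.
- **Lag knots** are `exp(k·log L/(m+1))`, i.e. equally spaced in `log` on
  `[1, L]` with boundary knots at lags 0 and L. Whether log-spacing should
  be computed on `lag+1` is genuinely ambiguous; this formula is fixed and
  configurable via an explicit `SplineSpec`.
- **Rows without full lag history** (the first L weeks) are excluded from
  fitting rather than back-filled.
- **Trend df selection** ("auto") refits the model over a candidate grid of
  df/year (default 1–6) and minimises `Σ_{l=1..52} |PACF_l|` of the
  *deviance* residuals (Pearson optional), ties toward the smaller df.
- **Exposure knots are shared across districts by default** (33rd/67th
  percentiles of the pooled temperature distribution). With per-district
  knots the pooled coefficient vector mixes slightly different bases;
  replicated synthetic runs showed this attenuates the pooled cumulative
  curve and manufactures apparent heterogeneity, so the comparable-basis
  default was adopted. Per-district knots remain available
  (`common_knots=False`) for sensitivity.
- **The region-level curve** evaluates the pooled coefficients on the basis
  built from the concatenated district weekly temperatures, centred at the
  region MRT. BLUP curves are re-centred at each district's own MRT.
- **Lag structure** pools, for each lag *l*, the district vectors `Θ C(l)`
  (full-rank, unlike the stacked per-lag log-RR vector, whose covariance
  has rank vl < L+1) with the same intercept-only meta-analysis; the
  reference is the regional average of district MRTs.

## Synthetic generator

The generator emulates a three-district tropical setting over 625 weeks
(≈12 years):

- **Weather.** Daily temperature = 28 °C + district offset (+0.5, −0.6,
  +0.1 °C) + annual sinusoid (amplitude 2 °C, peak near day 130) + AR(1)
  noise (daily sd 0.9, ρ 0.7); weekly block means then span ≈ 24–32 °C with
  mean ≈ 28 °C. Dew point sits 4.5 °C below temperature plus an independent
  AR(1) humidity component (daily sd 1.6, ρ 0.75), so weekly dew point
  correlates ≈ 0.8 with temperature — strong enough to act as a genuine
  confounder spline, without being collinear with the exposure.
- **Truth surface.** The cumulative log-RR is piecewise quadratic around
  its minimum at 28.0 °C, reaching RR 1.5 at the 30.4 °C anchor and RR 1.2
  at the 25.8 °C anchor — a J shape steeper above the minimum. Lag weights
  (0.40, 0.25, 0.15, 0.12, 0.08) spread the effect over lags 0–4 and sum to
  one, so the fitted overall cumulative curve targets exactly the truth
  function.
- **Counts.** Weekly log-mean = log(4) + lag-weighted truth + a mild annual
  harmonic (amplitude 0.10 on the log scale) + a slow trend (+0.10 log over
  the window); draws are negative binomial with per-observation size
  `μ/(φ−1)` so that Var = φ·μ locally, matching the quasi-Poisson variance
  function with φ = 1.5. (Quasi-likelihood has no generative model; a
  single global NB size cannot reproduce Var = φμ across means, the
  per-observation size can.) Weekly means land in the 2–9 band.
- **Line list.** Weekly severe counts are spread uniformly over the week's
  days with A00–A09 codes and severity flags; non-severe admissions are
  added so severe cases are 75% of in-scope admissions in expectation, plus
  out-of-scope decoy records that must never be counted.

What the generator does *not* emulate: aetiology mixtures with
pathogen-specific seasonality, reporting artifacts, holiday effects on
counts (the holiday column is exercised with synthetic calendars in unit
tests but the default generator emits none), spatial correlation between
districts beyond the shared truth surface, and rainfall. Passing tests
therefore demonstrate correctness of the inference chain under the stated
data-generating assumptions, not robustness to every feature of real
surveillance data.

## Problem sizes and numerical choices

Replicated checks use 100 studies of 3 × 625 weeks for parameter recovery
and homogeneity, and 200 (100 null + 100 with effect) for interval
calibration; a single study fits three ~60-parameter GLMs on ~621
observations each, so a full two-stage replicate runs in about two seconds.
The curve-recovery comparison evaluates the pooled curve against the truth
at the realised 95th temperature percentile *with the true MRT as
reference*: referencing at the estimated curve minimum adds the (real,
expected) upward selection noise of taking a minimum of a noisy curve,
which is a property of the reporting convention rather than of the curve
estimator being validated.

IRLS iterates to a relative deviance change below 1e−9 (cap 100
iterations) and flags non-convergence as an error; rank deficiency is
detected by pivoted QR and reported with the offending columns. The REML
surface is optimised to a gradient tolerance of 1e−7. Degenerate inputs:
a single district short-circuits stage two (μ = η₁, Ψ = 0, Q = 0); constant
residual series make the PACF undefined and raise; duplicate percentile
knots (constant temperatures) raise with a suggestion to use fewer knots.

## Known limitations

- The Wald intervals ignore uncertainty in Ψ (k = 3 districts gives it
  little information); coverage is nevertheless within the calibrated band
  in the replicated checks.
- Quasi-Poisson inference assumes independence given the model;
  autocorrelation not captured by the seasonal spline would deflate the
  standard errors.
- With per-district knots the pooled curve is an approximation (see design
  choices); with shared knots districts with atypical temperature ranges
  are extrapolated linearly beyond their own observed range.
- The MRT of a near-flat curve is weakly identified and its reported value
  can sit on a trimming bound.
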