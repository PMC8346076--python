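# dlagheat

Two-stage time-series modelling of the association between ambient
temperature and severe diarrhoea counts, of the kind used to study
climate-sensitive infectious disease in tropical cities.

## The problem and the method

Severe diarrhoea (deaths, and hospital admissions complicated by
dehydration and/or co-morbidity) responds to ambient temperature
non-linearly and with a delay of several weeks. The standard analysis for
multi-location weekly count data is:

**Stage one — per district.** A quasi-Poisson generalised linear model with
log link,

```
ln E[D_t] = α + cb(temp_t) + ns(dewp_t) + ns(t) + holiday_t
```

where `cb(temp)` is a distributed-lag non-linear model (DLNM) cross-basis:
a tensor product of a natural cubic spline in temperature (knots at the
33rd/67th percentiles of the observed distribution) and a natural cubic
spline in the lag dimension (intercept plus three knots equally spaced on
the log-lag scale, lags 0–4 weeks). `ns(dewp)` is a 3-df dew-point
confounder spline, `ns(t)` a seasonality/long-term-trend spline with 3 df
per year (optionally chosen by minimising the summed absolute partial
autocorrelation of the residuals), and `holiday` counts national holidays
per week. Overdispersion is absorbed by the Pearson dispersion
φ = χ²/(n−p) which scales the coefficient covariance.

**Reduction.** The fitted cross-basis coefficients are collapsed over the
lag axis to the *overall cumulative* exposure–response: a coefficient
vector η on the exposure spline with covariance Σ.

**Stage two — pooling.** District (η, Σ) pairs are combined with an
intercept-only multivariate random-effects meta-analysis estimated by REML;
heterogeneity is reported as Cochran Q and I², and best linear unbiased
predictions (BLUPs) shrink each district toward the pool. The pooled curve
is re-centred at the minimum-risk temperature (MRT: the curve minimum
between the 1st and 99th temperature percentiles) and summarised as
relative risks at the 95th ("high") and 5th ("low") temperature percentiles
with Wald 95% intervals, plus a per-lag breakdown of the association.

A synthetic-data generator produces three tropical districts (~12 years of
weekly data, weekly mean temperatures ≈ 24–32 °C around 28 °C, weekly count
means ≈ 2–9 with overdispersion) from a known J-shaped truth surface, so the
entire inference chain is testable against ground truth.

## Worked example

```python
import dlagheat as dh

weekly = dh.simulate_study(seed=4)          # 3 districts x 625 weeks
report = dh.run_two_stage(weekly, dh.AnalysisConfig())

s = report.ncr_summary
print(f"pooled MRT        {s.mrt:.2f} C")
print(f"RR at 95th pct    {s.rr_ht[0]:.3f} ({s.rr_ht[1]:.3f}, {s.rr_ht[2]:.3f})")
print(f"RR at 5th pct     {s.rr_lt[0]:.3f} ({s.rr_lt[1]:.3f}, {s.rr_lt[2]:.3f})")
print(f"I^2               {report.meta.i2:.1f}%")
```

prints

```
pooled MRT        27.88 C
RR at 95th pct    1.708 (1.300, 2.244)
RR at 5th pct     1.217 (0.954, 1.553)
I^2               0.0%
```

The generating truth here has its minimum at 28.0 °C and a cumulative RR of
1.5 at the high-temperature anchor, so the pooled curve recovers the MRT to
about 0.1 °C and the high-temperature risk within its confidence band; the
RR at the 95th percentile reads as a (1.708 − 1) × 100 ≈ 71% risk increase
relative to the MRT on this replicate, and I² = 0 reflects the shared truth
surface across districts (it is noisy with only three districts on any
single replicate).

The same analysis is scriptable from the shell:

```sh
dlagheat simulate --n-weeks 625 --seed 1 --out sim/
dlagheat fit --weekly sim/weekly.csv --out report/
dlagheat sensitivity --weekly sim/weekly.csv
```

`report/` then contains `table2.csv` (district + region MRT/RR summary),
`lagstructure.csv`, `curves/ncr.csv` and a `run.json` log. Real data enter
through `dlagheat prep`, which classifies a line-list CSV (ICD-10 A00–A09,
dehydration/co-morbidity flags), imputes missing station weather by
cross-station regression with annual harmonics, and aggregates everything
into district-weeks.

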