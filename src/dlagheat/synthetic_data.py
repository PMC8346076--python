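"""Synthetic multi-district weekly data with a known exposure-lag-response truth.

The generator emulates the study setting: three tropical urban districts
observed for about twelve years (625 weeks), daily mean temperature
following an annual sinusoid around 28 C with district offsets and AR(1)
noise so that weekly means span roughly 24-32 C; dew point a few degrees
below temperature; weekly severe-case counts with means in the 2-9 range
and moderate overdispersion; and a J-shaped cumulative temperature
association whose minimum sits near the centre of the temperature
distribution, rising faster above it than below.

Counts are drawn negative-binomial as a generative stand-in for the
quasi-Poisson variance assumption: the NB size parameter is chosen per
observation so that Var = phi * mu locally at each mean, which matches the
quasi-Poisson variance function (NB's mu + mu^2/size cannot match globally
with a single size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
WEEKS_PER_YEAR = DAYS_PER_YEAR / 7.0


@dataclass(frozen=True)
class TruthSurface:
    """Ground-truth cumulative exposure-lag-response used to generate counts.

    The cumulative log relative risk is piecewise quadratic around the true
    minimum-risk temperature ``mrt_true``: it reaches ``log(rr_high)`` at the
    anchor ``t_high`` and ``log(rr_low)`` at ``t_low``, with the high side
    steeper (a J shape when ``rr_high > rr_low``).  ``lag_weights`` spread
    the cumulative effect over lags 0..L and sum to one, so the fitted
    overall cumulative curve targets exactly this function.
    """

    mrt_true: float = 28.0
    rr_high: float = 1.5
    t_high: float = 30.4
    rr_low: float = 1.2
    t_low: float = 25.8
    lag_weights: tuple[float, ...] = (0.40, 0.25, 0.15, 0.12, 0.08)
    phi_true: float = 1.5
    baseline_mean: float = 4.0
    seasonal_amplitude: float = 0.10
    trend_log_slope: float = 0.10  # total log change over the whole window
    district_offsets: tuple[float, ...] = (0.5, -0.6, 0.1)

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("lag_weights must be non-negative and sum to 1")
        if not self.t_low < self.mrt_true < self.t_high:
            raise ValueError("need t_low < mrt_true < t_high")
        if self.phi_true < 1.0:
            raise ValueError("phi_true must be >= 1")

    @property
    def max_lag(self) -> int:
        return len(self.lag_weights) - 1

    def log_rr(self, x) -> np.ndarray:
        """Cumulative log relative risk at temperature ``x`` (vs the MRT)."""
        x = np.asarray(x, dtype=float)
        above = np.log(self.rr_high) * ((x - self.mrt_true) / (self.t_high - self.mrt_true)) ** 2
        below = np.log(self.rr_low) * ((self.mrt_true - x) / (self.mrt_true - self.t_low)) ** 2
        return np.where(x >= self.mrt_true, above, below)

    def to_dict(self) -> dict:
        return {
            "mrt_true": self.mrt_true, "rr_high": self.rr_high, "t_high": self.t_high,
            "rr_low": self.rr_low, "t_low": self.t_low,
            "lag_weights": list(self.lag_weights), "phi_true": self.phi_true,
            "baseline_mean": self.baseline_mean,
            "seasonal_amplitude": self.seasonal_amplitude,
            "trend_log_slope": self.trend_log_slope,
            "district_offsets": list(self.district_offsets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSurface":
        d = dict(d)
        for key in ("lag_weights", "district_offsets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


DEFAULT_DISTRICTS = ("capital", "eastern", "southern")


def simulate_weather(
    n_weeks: int = 625,
    district_offsets: tuple[float, ...] = (0.5, -0.6, 0.1),
    seed: int = 0,
    start: date = date(2006, 1, 1),
    annual_amplitude: float = 2.0,
    ar_rho: float = 0.7,
    ar_sd: float = 0.9,
    mean_tmean: float = 28.0,
    dewp_gap: float = 4.5,
    dewp_ar_sd: float = 1.6,
    districts: tuple[str, ...] = DEFAULT_DISTRICTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily and weekly temperature/dew point series for each district.

    Daily temperature = annual sinusoid (peak in early May, as in a
    monsoonal tropical climate) + district offset + AR(1) noise; dew point
    sits ``dewp_gap`` below temperature with its own persistent AR(1)
    humidity variation, which is wider than the temperature noise so the
    dew-point confounder is correlated with but not collinear to the
    exposure.  Returns ``(daily, weekly)`` frames; the weekly frame holds
    7-day block means.
    """
    if n_weeks < 104:
        raise ValueError("need at least two years of weeks")
    if len(district_offsets) != len(districts):
        raise ValueError("one offset per district required")
    rng = np.random.default_rng(seed)
    n_days = n_weeks * 7
    dates = pd.to_datetime(start) + pd.to_timedelta(np.arange(n_days), unit="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    season = annual_amplitude * np.cos(2 * np.pi * (doy - 130.0) / DAYS_PER_YEAR)

    def ar1(sd: float, rho: float) -> np.ndarray:
        noise = np.empty(n_days)
        innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), n_days)
        noise[0] = rng.normal(0.0, sd)
        for i in range(1, n_days):
            noise[i] = rho * noise[i - 1] + innov[i]
        return noise

    daily_rows = []
    for dist, off in zip(districts, district_offsets):
        tmean = mean_tmean + off + season + ar1(ar_sd, ar_rho)
        dewp = tmean - dewp_gap + ar1(dewp_ar_sd, 0.75)
        daily_rows.append(pd.DataFrame({
            "date": dates, "station": f"station_{dist}", "district": dist,
            "tmean": tmean, "dewp": dewp, "rain": np.nan,
        }))
    daily = pd.concat(daily_rows, ignore_index=True)

    daily["_week"] = np.tile(np.repeat(np.arange(n_weeks), 7), len(districts))
    weekly = (
        daily.groupby(["district", "_week"], sort=True)
        .agg(tmean_wk=("tmean", "mean"), dewp_wk=("dewp", "mean"))
        .reset_index()
        .rename(columns={"_week": "t"})
    )
    weekly["week_start"] = weekly["t"].map(
        lambda w: (pd.Timestamp(start) + timedelta(days=7 * int(w))).date()
    )
    return daily.drop(columns="_week"), weekly


def simulate_counts(
    weekly: pd.DataFrame,
    truth: TruthSurface,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw weekly counts from the truth surface given weekly temperatures.

    The weekly log mean is baseline + the lag-weighted cumulative log-RR of
    current and past temperatures + a mild annual harmonic + a slow log
    trend.  The first ``max_lag`` weeks lack full lag history and are
    emitted with ``valid = False``.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(truth.lag_weights)
    L = truth.max_lag
    out = []
    for dist, grp in weekly.groupby("district", sort=True):
        grp = grp.sort_values("t").reset_index(drop=True)
        x = grp["tmean_wk"].to_numpy()
        n = len(x)
        f = truth.log_rr(x)
        effect = np.full(n, np.nan)
        for t in range(L, n):
            effect[t] = w @ f[t - np.arange(L + 1)]
        tt = grp["t"].to_numpy(dtype=float)
        eta = (
            np.log(truth.baseline_mean)
            + truth.seasonal_amplitude * np.cos(2 * np.pi * tt / WEEKS_PER_YEAR)
            + truth.trend_log_slope * tt / n
            + np.where(np.isnan(effect), 0.0, effect)
        )
        mu = np.exp(eta)
        if np.any(mu > 1e6):
            raise ValueError("mean count overflow; check truth parameters")
        if truth.phi_true > 1.0:
            size = mu / (truth.phi_true - 1.0)  # Var = mu + mu^2/size = phi*mu
            counts = rng.negative_binomial(size, size / (size + mu))
        else:
            counts = rng.poisson(mu)
        res = grp.copy()
        res["count"] = counts.astype(int)
        res["mu_true"] = mu
        res["valid"] = np.arange(n) >= L
        out.append(res)
    return pd.concat(out, ignore_index=True)


def make_line_list(
    weekly_counts: pd.DataFrame,
    severe_fraction: float = 0.75,
    decoy_rate: float = 0.05,
    seed: int = 0,
    count_col: str = "count",
) -> pd.DataFrame:
    """Expand weekly severe counts into an admission line list.

    Each week's ``count`` severe admissions are spread uniformly over the
    week's 7 days with A00-A09 codes and a dehydration and/or co-morbidity
    flag; extra non-severe admissions are added so severe cases form
    ``severe_fraction`` of all A00-A09 admissions in expectation, plus a few
    decoy records with out-of-scope ICD codes that must never be counted.
    """
    if not 0 < severe_fraction <= 1:
        raise ValueError("severe_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    icd_severe = np.array([f"A0{i}" for i in range(10)])
    rows = []
    for rec in weekly_counts.itertuples():
        start = pd.Timestamp(rec.week_start)
        k = int(getattr(rec, count_col))
        n_nonsev = rng.poisson(k * (1 - severe_fraction) / severe_fraction)
        n_decoy = rng.poisson(max(k, 1) * decoy_rate)
        for kind, n in (("severe", k), ("non_severe", n_nonsev), ("decoy", n_decoy)):
            if n == 0:
                continue
            days = rng.integers(0, 7, n)
            for d in days:
                if kind == "decoy":
                    icd = rng.choice(["J18", "K52.9", "B99", "R19"])
                    dehyd = comorb = bool(rng.random() < 0.5)
                else:
                    icd = str(rng.choice(icd_severe))
                    if kind == "severe":
                        u = rng.random()
                        dehyd = u < 0.8
                        comorb = (not dehyd) or (rng.random() < 0.3)
                    else:
                        dehyd = comorb = False
                rows.append({
                    "event_date": (start + timedelta(days=int(d))).date(),
                    "district": rec.district,
                    "icd10": icd,
                    "outcome": "admission",
                    "dehydration": dehyd,
                    "comorbidity": comorb,
                })
    return pd.DataFrame(rows, columns=[
        "event_date", "district", "icd10", "outcome", "dehydration", "comorbidity",
    ])


def simulate_study(
    truth: TruthSurface | None = None,
    n_weeks: int = 625,
    seed: int = 0,
    outcome_col: str = "severe_admissions",
) -> pd.DataFrame:
    """One full synthetic study: weekly weather plus counts for 3 districts.

    Returns a weekly frame with the columns the pipeline consumes
    (district, t, week_start, tmean_wk, dewp_wk, the outcome count columns
    and a zero holiday column).
    """
    truth = truth or TruthSurface()
    ss = np.random.SeedSequence(seed)
    s_weather, s_counts = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    _, weekly = simulate_weather(
        n_weeks=n_weeks, district_offsets=truth.district_offsets, seed=s_weather
    )
    counts = simulate_counts(weekly, truth, seed=s_counts)
    counts = counts.rename(columns={"count": outcome_col})
    for col in ("deaths", "severe_admissions", "all_admissions"):
        if col not in counts.columns:
            counts[col] = counts[outcome_col]
    counts["holidays"] = 0
    counts["rain_wk"] = np.nan
    return counts
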