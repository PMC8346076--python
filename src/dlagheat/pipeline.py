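"""Two-stage orchestration: district fits, pooling, curves and tables.

Stage one fits, per district, a quasi-Poisson regression of weekly counts on
the temperature cross-basis plus a dew-point natural spline, a
seasonality/trend spline of the week index and a holiday term, then reduces
the cross-basis coefficients to the overall cumulative curve.  Stage two
pools the district curves by intercept-only multivariate meta-analysis,
derives BLUP curves re-centred at each district's minimum-risk temperature,
the region-level pooled curve and relative-risk table, and the lag
structure of the association at the high/low percentile temperatures.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mvmeta
from .basis import SplineSpec, knots_by_percentile, ns_eval, trend_spline_spec
from .crossbasis import (
    CrossBasisSpec,
    ReducedCurve,
    build_crossbasis,
    crossbasis_spec_from_temps,
    lag_slice,
    reduce_overall,
)
from .curve_reduce import (
    ExposureResponseCurve,
    RRSummary,
    centred_curve,
    find_mrt,
    rr_at_percentiles,
)
from .qpglm import FirstStageFit, fit_quasipoisson, select_trend_df
from .synthetic_data import WEEKS_PER_YEAR

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    outcome: str = "severe_admissions"  # deaths | severe_admissions | all_admissions
    max_lag: int = 4
    trend_df_per_year: int | str = 3  # integer or "auto" (residual-PACF search)
    trend_df_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    dewp_df: int = 3
    exposure_knot_pcts: tuple[float, float] = (33.0, 67.0)
    n_lag_knots: int = 3
    rr_pcts: tuple[float, float] = (5.0, 95.0)
    mrt_bounds_pcts: tuple[float, float] = (1.0, 99.0)
    include_rain: bool = False
    common_knots: bool = True  # exposure knots from pooled temps; per-district knots optional
    meta_method: str = "reml"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        for p in (*self.exposure_knot_pcts, *self.rr_pcts, *self.mrt_bounds_pcts):
            if not 0 < p < 100:
                raise ValueError("percentiles must lie in (0, 100)")
        if self.outcome not in ("deaths", "severe_admissions", "all_admissions"):
            raise ValueError(f"unknown outcome {self.outcome!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("trend_df_candidates", "exposure_knot_pcts", "rr_pcts", "mrt_bounds_pcts"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class DistrictFirstStage:
    district: str
    fit: FirstStageFit
    curve: ReducedCurve
    cb_spec: CrossBasisSpec
    cb_slice: slice  # columns of the cross-basis block in the design
    trend_df_per_year: int


@dataclass
class RunReport:
    config: AnalysisConfig
    first_stage: dict[str, DistrictFirstStage]
    meta: mvmeta.MetaResult
    blup_curves: dict[str, ReducedCurve]
    district_mrt: dict[str, float]
    district_summary: dict[str, RRSummary]
    ncr_curve: ExposureResponseCurve
    ncr_summary: RRSummary
    lag_table: pd.DataFrame

    def table2(self) -> pd.DataFrame:
        """Headline relative-risk table: one row per district plus the region."""
        rows = []
        for name, s in {**self.district_summary, "NCR": self.ncr_summary}.items():
            rows.append({
                "location": name,
                "pct95_temp": s.pct95_temp, "pct5_temp": s.pct5_temp, "mrt": s.mrt,
                "rr_ht": s.rr_ht[0], "rr_ht_lo": s.rr_ht[1], "rr_ht_hi": s.rr_ht[2],
                "rr_lt": s.rr_lt[0], "rr_lt_lo": s.rr_lt[1], "rr_lt_hi": s.rr_lt[2],
            })
        return pd.DataFrame(rows)


def _district_frames(weekly: pd.DataFrame) -> dict[str, pd.DataFrame]:
    frames = {}
    for dist, grp in weekly.groupby("district", sort=True):
        grp = grp.sort_values("t").reset_index(drop=True)
        if not np.array_equal(grp["t"].to_numpy(), np.arange(len(grp))):
            raise ValueError(f"district {dist} weeks are not contiguous from 0")
        frames[str(dist)] = grp
    return frames


def build_design(
    grp: pd.DataFrame,
    config: AnalysisConfig,
    cb_spec: CrossBasisSpec,
    trend_df_per_year: int,
) -> tuple[np.ndarray, np.ndarray, slice]:
    """Design matrix for one district (valid rows only) and the cross-basis slice."""
    n = len(grp)
    cb = build_crossbasis(grp["tmean_wk"].to_numpy(), cb_spec)
    valid = cb.valid_rows

    dewp = grp["dewp_wk"].to_numpy()
    dewp_spec = SplineSpec(
        knots=tuple(knots_by_percentile(dewp, np.linspace(0, 100, config.dewp_df + 1)[1:-1])),
        boundary=(float(dewp.min()), float(dewp.max())),
    )
    dewp_basis = ns_eval(dewp, dewp_spec).values

    trend_df = max(2, int(round(trend_df_per_year * n / WEEKS_PER_YEAR)))
    trend_basis = ns_eval(
        grp["t"].to_numpy(dtype=float), trend_spline_spec(n, trend_df)
    ).values

    blocks = [np.ones((n, 1)), cb.values, dewp_basis, trend_basis]
    cb_slice = slice(1, 1 + cb_spec.n_columns)
    holidays = grp["holidays"].to_numpy(dtype=float) if "holidays" in grp else np.zeros(n)
    if holidays.any():
        blocks.append(holidays[:, None])
    if config.include_rain:
        rain = grp.get("rain_wk")
        rain = np.nan_to_num(rain.to_numpy(dtype=float)) if rain is not None else np.zeros(n)
        if rain.any():
            blocks.append(rain[:, None])
    X = np.column_stack(blocks)
    y = grp[config.outcome].to_numpy(dtype=float)
    return y[valid], X[valid], cb_slice


def run_first_stage(
    weekly: pd.DataFrame, config: AnalysisConfig
) -> dict[str, DistrictFirstStage]:
    """Fit the first-stage model in every district and reduce to curves."""
    frames = _district_frames(weekly)
    for dist, grp in frames.items():
        if len(grp) <= 5 * 52:  # need several seasonal cycles per district
            raise ValueError(
                f"district {dist} has only {len(grp)} weeks; at least "
                f"{5 * 52 + 1} are required for a stable seasonal fit"
            )
    pooled_temps = weekly["tmean_wk"].to_numpy()
    results: dict[str, DistrictFirstStage] = {}
    for dist, grp in frames.items():
        temps = pooled_temps if config.common_knots else grp["tmean_wk"].to_numpy()
        cb_spec = crossbasis_spec_from_temps(
            temps, max_lag=config.max_lag,
            exposure_knot_pcts=config.exposure_knot_pcts,
            n_lag_knots=config.n_lag_knots,
        )
        if config.trend_df_per_year == "auto":
            y_all, _, _ = build_design(grp, config, cb_spec, 1)

            def make_design(df_per_year, _grp=grp, _cb=cb_spec):
                return build_design(_grp, config, _cb, df_per_year)[1]

            trend_df, _ = select_trend_df(y_all, make_design, config.trend_df_candidates)
        else:
            trend_df = int(config.trend_df_per_year)
        y, X, cb_slice = build_design(grp, config, cb_spec, trend_df)
        fit = fit_quasipoisson(y, X)
        theta = fit.coef[cb_slice]
        vcov = fit.vcov[cb_slice, cb_slice]
        curve = reduce_overall(theta, vcov, cb_spec)
        results[dist] = DistrictFirstStage(
            district=dist, fit=fit, curve=curve, cb_spec=cb_spec,
            cb_slice=cb_slice, trend_df_per_year=trend_df,
        )
    return results


def _ncr_exposure_spec(weekly: pd.DataFrame, config: AnalysisConfig) -> SplineSpec:
    temps = weekly["tmean_wk"].to_numpy()
    return SplineSpec(
        knots=tuple(knots_by_percentile(temps, config.exposure_knot_pcts)),
        boundary=(float(temps.min()), float(temps.max())),
    )


def run_two_stage(weekly: pd.DataFrame, config: AnalysisConfig) -> RunReport:
    """Full analysis: district fits, pooling, BLUPs, tables and lag structure."""
    stage1 = run_first_stage(weekly, config)
    districts = list(stage1)
    curves = [stage1[d].curve for d in districts]
    dims = {len(c.eta) for c in curves}
    if len(dims) > 1:
        raise ValueError(
            "district curves have incompatible dimensions; set common_knots=True"
        )
    meta = mvmeta.meta_fit(curves, method=config.meta_method)

    blups = mvmeta.blup_curves(meta, curves)
    frames = _district_frames(weekly)
    pooled_temps = weekly["tmean_wk"].to_numpy()

    blup_by_d: dict[str, ReducedCurve] = {}
    mrt_by_d: dict[str, float] = {}
    summary_by_d: dict[str, RRSummary] = {}
    for dist, blup in zip(districts, blups):
        temps = frames[dist]["tmean_wk"].to_numpy()
        mrt = find_mrt(blup, temps, config.mrt_bounds_pcts)
        blup_by_d[dist] = blup
        mrt_by_d[dist] = mrt
        summary_by_d[dist] = rr_at_percentiles(
            blup, temps, mrt, pcts=config.rr_pcts
        )

    # region-level association: pooled coefficients on the pooled-temperature basis
    ncr_spec = _ncr_exposure_spec(weekly, config)
    ncr_reduced = ReducedCurve(
        eta=meta.mu, sigma=meta.mu_vcov, exposure_spec=ncr_spec,
        temp_range=(float(pooled_temps.min()), float(pooled_temps.max())),
    )
    ncr_mrt = find_mrt(ncr_reduced, pooled_temps, config.mrt_bounds_pcts)
    ncr_summary = rr_at_percentiles(ncr_reduced, pooled_temps, ncr_mrt, pcts=config.rr_pcts)
    lo, hi = np.percentile(pooled_temps, config.mrt_bounds_pcts)
    grid = np.linspace(lo, hi, 200)
    ncr_curve = centred_curve(ncr_reduced, grid, ncr_mrt, source="pooled")

    lag_table = lag_structure(stage1, weekly, mrt_by_d, config)
    return RunReport(
        config=config, first_stage=stage1, meta=meta,
        blup_curves=blup_by_d, district_mrt=mrt_by_d, district_summary=summary_by_d,
        ncr_curve=ncr_curve, ncr_summary=ncr_summary, lag_table=lag_table,
    )


def lag_structure(
    stage1: dict[str, DistrictFirstStage],
    weekly: pd.DataFrame,
    district_mrt: dict[str, float],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-lag pooled relative risks at the high/low percentile temperatures.

    The reference is the regional average of district MRTs.  For each lag
    ``l`` the district-specific lag-slice coefficient vectors ``Theta C(l)``
    (with their delta-method covariances) are pooled with the same
    intercept-only meta-analysis used for the cumulative curves; the pooled
    vector then gives the log-RR of the percentile temperature versus the
    reference at that lag.
    """
    from .curve_reduce import WALD_Z

    pooled_temps = weekly["tmean_wk"].to_numpy()
    t_lo, t_hi = np.percentile(pooled_temps, config.rr_pcts)
    ref = float(np.mean(list(district_mrt.values())))
    L = config.max_lag

    rows = []
    for lag in range(L + 1):
        per_district = []
        for d, s in stage1.items():
            theta = s.fit.coef[s.cb_slice]
            vcov = s.fit.vcov[s.cb_slice, s.cb_slice]
            C = s.cb_spec.lag_basis()
            B = np.kron(np.eye(s.cb_spec.vx), C[lag])  # theta_l = Theta C(l)
            per_district.append(
                ReducedCurve(
                    eta=B @ theta, sigma=B @ vcov @ B.T,
                    exposure_spec=s.cb_spec.exposure, temp_range=s.curve.temp_range,
                )
            )
        pooled = mvmeta.meta_fit(per_district, method=config.meta_method)
        any_spec = next(iter(stage1.values())).cb_spec
        for label, x_at in (("high", float(t_hi)), ("low", float(t_lo))):
            dvec = (any_spec.exposure_basis(x_at) - any_spec.exposure_basis(ref))[0]
            log_rr = float(dvec @ pooled.mu)
            se = float(np.sqrt(max(dvec @ pooled.mu_vcov @ dvec, 0.0)))
            rows.append({
                "temperature": label, "temp_c": x_at, "ref_c": ref, "lag": lag,
                "rr": float(np.exp(log_rr)),
                "rr_lo": float(np.exp(log_rr - WALD_Z * se)),
                "rr_hi": float(np.exp(log_rr + WALD_Z * se)),
            })
    return pd.DataFrame(rows).sort_values(["temperature", "lag"], ignore_index=True)


def sensitivity_sweep(
    weekly: pd.DataFrame,
    base: AnalysisConfig,
    max_lags: tuple[int, ...] = (4, 7),
    trend_dfs: tuple[int, ...] = (3, 4, 5, 6),
) -> pd.DataFrame:
    """Re-run the two-stage analysis over alternative lag/trend settings.

    Returns one row per configuration with the region-level MRT and
    high/low-temperature relative risks, for checking curve-shape stability.
    """
    rows = []
    for L in max_lags:
        for df in trend_dfs:
            cfg = dataclasses.replace(base, max_lag=L, trend_df_per_year=df)
            rep = run_two_stage(weekly, cfg)
            s = rep.ncr_summary
            rows.append({
                "max_lag": L, "trend_df_per_year": df,
                "mrt": s.mrt, "rr_ht": s.rr_ht[0], "rr_lt": s.rr_lt[0],
                "rr_ht_lo": s.rr_ht[1], "rr_ht_hi": s.rr_ht[2],
            })
    return pd.DataFrame(rows)
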