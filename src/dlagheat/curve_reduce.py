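"""Centred cumulative exposure-response curves, minimum-risk temperature,
and percentile relative risks with Wald confidence intervals.

All quantities derive from a reduced coefficient vector ``eta`` on the
exposure spline basis ``b``: the cumulative log relative risk of ``x``
versus a reference ``ref`` is ``(b(x) - b(ref)) @ eta`` with variance
``(b(x) - b(ref)) @ sigma @ (b(x) - b(ref))`` (delta method).  The minimum
risk temperature (MRT) is the minimiser of the curve on a fine grid between
trimmed percentiles of the observed temperatures, and relative risks are
reported at the 5th and 95th temperature percentiles versus the MRT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import ns_eval
from .crossbasis import ReducedCurve

WALD_Z = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ExposureResponseCurve:
    grid: np.ndarray  # degrees C
    log_rr: np.ndarray
    se: np.ndarray
    ref: float
    source: str = "district"  # district | pooled | blup

    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.exp(self.log_rr - WALD_Z * self.se),
            np.exp(self.log_rr + WALD_Z * self.se),
        )


@dataclass(frozen=True)
class RRSummary:
    """Table layout of the headline numbers: percentile temperatures, MRT,
    and the relative risks at high/low temperature with 95% CI."""

    pct95_temp: float
    pct5_temp: float
    mrt: float
    rr_ht: tuple[float, float, float]  # point, lo, hi
    rr_lt: tuple[float, float, float]


def _basis_diff(curve: ReducedCurve, x: np.ndarray, ref: float) -> np.ndarray:
    b = ns_eval(np.atleast_1d(np.asarray(x, dtype=float)), curve.exposure_spec).values
    bref = ns_eval(np.array([float(ref)]), curve.exposure_spec).values[0]
    return b - bref


def centred_curve(
    curve_coef: ReducedCurve,
    grid: np.ndarray,
    ref: float,
    source: str = "district",
) -> ExposureResponseCurve:
    """Cumulative log-RR curve re-centred at ``ref`` with delta-method SEs."""
    grid = np.asarray(grid, dtype=float)
    d = _basis_diff(curve_coef, grid, ref)
    log_rr = d @ curve_coef.eta
    var = np.einsum("ij,jk,ik->i", d, curve_coef.sigma, d)
    se = np.sqrt(np.maximum(var, 0.0))
    return ExposureResponseCurve(grid=grid, log_rr=log_rr, se=se, ref=float(ref), source=source)


def find_mrt(
    curve_coef: ReducedCurve,
    temps: np.ndarray,
    bounds_pct: tuple[float, float] = (1.0, 99.0),
    grid_step: float = 0.01,
) -> float:
    """Minimum-risk temperature on a fine grid between trimmed percentiles.

    Evaluates the (uncentred) cumulative curve on a ``grid_step``-spaced grid
    between the ``bounds_pct`` empirical percentiles of ``temps`` and returns
    the minimising temperature; ties break toward the lowest temperature.
    The result does not depend on any centring since only curve shape enters.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("temps must be non-empty")
    lo, hi = np.percentile(temps, bounds_pct)
    n_steps = int(np.floor((hi - lo) / grid_step + 1e-9))
    grid = lo + grid_step * np.arange(n_steps + 1)
    vals = ns_eval(grid, curve_coef.exposure_spec).values @ curve_coef.eta
    return float(grid[int(np.argmin(vals))])


def rr_at_percentiles(
    curve_coef: ReducedCurve,
    temps: np.ndarray,
    ref: float,
    pcts: tuple[float, float] = (5.0, 95.0),
    mrt_bounds_pct: tuple[float, float] = (1.0, 99.0),
) -> RRSummary:
    """Relative risks at the low/high percentile temperatures versus ``ref``.

    ``ref`` is normally the MRT from :func:`find_mrt`; Wald 95% intervals are
    ``exp(log_rr +/- 1.959964 * se)``.
    """
    temps = np.asarray(temps, dtype=float)
    t_lo, t_hi = np.percentile(temps, pcts)

    def one(x: float) -> tuple[float, float, float]:
        d = _basis_diff(curve_coef, np.array([x]), ref)[0]
        log_rr = float(d @ curve_coef.eta)
        se = float(np.sqrt(max(d @ curve_coef.sigma @ d, 0.0)))
        return (
            float(np.exp(log_rr)),
            float(np.exp(log_rr - WALD_Z * se)),
            float(np.exp(log_rr + WALD_Z * se)),
        )

    return RRSummary(
        pct95_temp=float(t_hi),
        pct5_temp=float(t_lo),
        mrt=float(ref),
        rr_ht=one(float(t_hi)),
        rr_lt=one(float(t_lo)),
    )


def curve_to_frame(curve: ExposureResponseCurve):
    """CSV-friendly view (temp, rr, lo, hi) of a centred curve."""
    import pandas as pd

    lo, hi = curve.ci()
    return pd.DataFrame(
        {"temp": curve.grid, "rr": curve.rr(), "lo": lo, "hi": hi}
    )
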