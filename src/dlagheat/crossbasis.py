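"""Exposure x lag cross-basis construction and its linear reductions.

The cross-basis is the tensor-product design block of a distributed-lag
non-linear model: its column ``(j, k)`` at week ``t`` is

    sum_{l=0..L} R_j(x_{t-l}) * C_k(l)

where ``R`` is the exposure spline basis evaluated at the lagged exposures
and ``C`` the lag spline basis evaluated at integer lags ``0..L``.  Because
the data are weekly, the lag axis is a finite sum rather than an integral.

Coefficient layout: the fitted coefficient vector over cross-basis columns
is stored exposure-major, index ``j * vl + k`` for exposure basis function
``j`` and lag basis function ``k``.  Both reduction operations below depend
on this layout and the second-stage pooling inherits it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import SplineSpec, knots_by_percentile, log_lag_knots, ns_eval


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure and lag spline definitions plus the maximum lag in weeks."""

    exposure: SplineSpec
    lag: SplineSpec
    max_lag: int

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")

    @property
    def vx(self) -> int:
        return self.exposure.df

    @property
    def vl(self) -> int:
        return self.lag.df

    @property
    def n_columns(self) -> int:
        return self.vx * self.vl

    def lag_basis(self) -> np.ndarray:
        """Lag basis evaluated at integer lags 0..L, shape (L+1, vl)."""
        return ns_eval(np.arange(self.max_lag + 1, dtype=float), self.lag).values

    def exposure_basis(self, x) -> np.ndarray:
        return ns_eval(np.atleast_1d(np.asarray(x, dtype=float)), self.exposure).values


def crossbasis_spec_from_temps(
    temps: np.ndarray,
    max_lag: int = 4,
    exposure_knot_pcts: tuple[float, float] = (33.0, 67.0),
    n_lag_knots: int = 3,
) -> CrossBasisSpec:
    """Standard cross-basis: exposure knots at temperature percentiles
    (boundary at the observed range), lag knots log-spaced with an
    intercepted lag basis on ``[0, max_lag]``."""
    temps = np.asarray(temps, dtype=float)
    exposure = SplineSpec(
        knots=tuple(knots_by_percentile(temps, exposure_knot_pcts)),
        boundary=(float(temps.min()), float(temps.max())),
        intercept=False,
    )
    lag = SplineSpec(
        knots=tuple(log_lag_knots(max_lag, n_lag_knots)),
        boundary=(0.0, float(max_lag)),
        intercept=True,
    )
    return CrossBasisSpec(exposure=exposure, lag=lag, max_lag=max_lag)


@dataclass(frozen=True)
class CrossBasisMatrix:
    values: np.ndarray  # (n, vx*vl)
    spec: CrossBasisSpec
    valid_rows: np.ndarray  # bool, False for the first L rows


@dataclass(frozen=True)
class ReducedCurve:
    """Overall-cumulative exposure-response coefficients for one district.

    ``eta`` lives on the exposure basis; a temperature's cumulative log
    relative risk versus a reference is ``(b(x) - b(ref)) @ eta``.
    """

    eta: np.ndarray  # (vx,)
    sigma: np.ndarray  # (vx, vx)
    exposure_spec: SplineSpec
    temp_range: tuple[float, float]

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.shape != (len(self.eta), len(self.eta)):
            raise ValueError("sigma shape does not match eta")
        if not np.allclose(sigma, sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")


def build_crossbasis(x: np.ndarray, spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Build the n x (vx*vl) cross-basis block for an exposure series.

    The first ``max_lag`` rows have incomplete lag history and are flagged
    invalid; they are excluded from fitting rather than back-filled.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    L = spec.max_lag
    if n <= L:
        raise ValueError(f"series length {n} must exceed max_lag {L}")
    R = spec.exposure_basis(x)  # (n, vx)
    C = spec.lag_basis()  # (L+1, vl)
    vx, vl = spec.vx, spec.vl
    values = np.zeros((n, vx * vl))
    for lag in range(L + 1):
        Rlag = np.empty_like(R)
        Rlag[lag:] = R[: n - lag]
        Rlag[:lag] = np.nan
        # outer product over (exposure j, lag-basis k) for this lag
        values += np.nan_to_num(Rlag[:, :, None] * C[lag][None, None, :]).reshape(n, -1)
    valid = np.arange(n) >= L
    values[~valid] = np.nan
    return CrossBasisMatrix(values=values, spec=spec, valid_rows=valid)


def _cumulative_map(spec: CrossBasisSpec) -> np.ndarray:
    """Linear map A with eta = A @ theta, summing the lag basis over lags."""
    M = spec.lag_basis().sum(axis=0)  # (vl,)
    return np.kron(np.eye(spec.vx), M)  # (vx, vx*vl)


def reduce_overall(theta: np.ndarray, vcov: np.ndarray, spec: CrossBasisSpec,
                   temp_range: tuple[float, float] | None = None) -> ReducedCurve:
    """Collapse the lag dimension: overall cumulative coefficients and covariance."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_columns,):
        raise ValueError(
            f"theta must have length vx*vl = {spec.n_columns}, got {theta.shape}"
        )
    vcov = np.asarray(vcov, dtype=float)
    if vcov.shape != (spec.n_columns, spec.n_columns):
        raise ValueError("vcov shape does not match theta")
    A = _cumulative_map(spec)
    rng = temp_range if temp_range is not None else spec.exposure.boundary
    return ReducedCurve(
        eta=A @ theta,
        sigma=A @ vcov @ A.T,
        exposure_spec=spec.exposure,
        temp_range=(float(rng[0]), float(rng[1])),
    )


def lag_slice(theta: np.ndarray, vcov: np.ndarray, spec: CrossBasisSpec,
              x_at: float, x_ref: float) -> tuple[np.ndarray, np.ndarray]:
    """Lag-specific log relative risks of ``x_at`` versus ``x_ref``.

    Returns ``(log_rr, var)`` over lags ``0..L``; temperatures outside the
    exposure boundary are extrapolated linearly by the natural spline.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_columns,):
        raise ValueError(f"theta must have length {spec.n_columns}")
    C = spec.lag_basis()
    d = (spec.exposure_basis(x_at) - spec.exposure_basis(x_ref))[0]  # (vx,)
    L = spec.max_lag
    log_rr = np.empty(L + 1)
    var = np.empty(L + 1)
    for lag in range(L + 1):
        a = np.kron(d, C[lag])
        log_rr[lag] = a @ theta
        var[lag] = a @ vcov @ a
    return log_rr, var
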