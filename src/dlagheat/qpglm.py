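"""First-stage overdispersed count regression and the residual-PACF criterion.

The first stage is a quasi-Poisson generalised linear model with log link:
the coefficient estimates solve the Poisson score equations (fitted here by
iteratively reweighted least squares), while the covariance is inflated by
the Pearson dispersion ``phi = chi^2_Pearson / (n - p)``.

The flexibility of the seasonality/trend spline is chosen by refitting the
model over a grid of degrees of freedom per year and minimising the sum of
absolute partial autocorrelations of the residuals, a standard check that
the spline has removed serial structure the model should explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg


class NonConvergenceError(RuntimeError):
    pass


@dataclass
class FirstStageFit:
    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    deviance_residuals: np.ndarray
    pearson_residuals: np.ndarray
    fitted: np.ndarray
    n_valid: int
    converged: bool
    n_iter: int


def _check_rank(X: np.ndarray) -> None:
    # pivoted QR exposes which columns are (numerically) collinear
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[diag < tol]
    if bad.size:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {sorted(bad.tolist())}"
        )


def fit_quasipoisson(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> FirstStageFit:
    """Fit a log-link quasi-Poisson regression by IRLS.

    ``y`` are non-negative counts, ``X`` the full design including the
    intercept column.  Iterates until the relative change in deviance and
    coefficients falls below ``tol``; non-convergence raises rather than
    returning a silently bad fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible shapes")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must contain non-negative integer counts")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X)

    # standard IRLS start: working response from the data themselves
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = np.zeros(p)
    dev = _poisson_deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu  # Poisson working weight with log link
        z = eta + (y - mu) / mu
        wx = X * np.sqrt(w)[:, None]
        wz = z * np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(wx, wz, rcond=None)
        eta = X @ beta_new
        mu = np.exp(np.clip(eta, -30, 30))
        dev_new = _poisson_deviance(y, mu)
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        rel_dev = abs(dev_new - dev) / max(abs(dev_new), 1e-12)
        beta, dev = beta_new, dev_new
        if rel_dev < tol and delta < np.sqrt(tol):
            converged = True
            break
    if not converged:
        raise NonConvergenceError(
            f"IRLS did not converge in {max_iter} iterations (deviance {dev:.6g})"
        )

    pearson = (y - mu) / np.sqrt(mu)
    phi = float(np.sum(pearson**2) / (n - p))
    xtwx = X.T @ (X * mu[:, None])
    vcov = phi * np.linalg.inv(xtwx)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = y * np.log(np.where(y > 0, y / mu, 1.0)) - (y - mu)
    devres = np.sign(y - mu) * np.sqrt(2.0 * np.maximum(unit, 0.0))
    return FirstStageFit(
        coef=beta,
        vcov=vcov,
        dispersion=phi,
        deviance_residuals=devres,
        pearson_residuals=pearson,
        fitted=mu,
        n_valid=n,
        converged=True,
        n_iter=it,
    )


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = y * np.log(np.where(y > 0, y / mu, 1.0)) - (y - mu)
    return float(2.0 * np.sum(unit))


def pacf(residuals: np.ndarray, max_lag: int) -> np.ndarray:
    """Partial autocorrelations at lags ``1..max_lag`` by Durbin-Levinson.

    Sample autocovariances use the biased (1/n) normalisation, so the
    recursion is equivalent to solving the Yule-Walker equations at each
    order.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if n <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    x = x - x.mean()
    c0 = float(x @ x) / n
    if c0 <= 0:
        raise ValueError("residuals are constant (zero variance)")
    rho = np.array([float(x[: n - k] @ x[k:]) / (n * c0) for k in range(max_lag + 1)])

    pac = np.empty(max_lag)
    phi_prev = np.empty(0)
    v = 1.0
    for k in range(1, max_lag + 1):
        if k == 1:
            a = rho[1]
        else:
            a = (rho[k] - phi_prev @ rho[k - 1 : 0 : -1]) / v
        pac[k - 1] = a
        phi = np.empty(k)
        phi[:-1] = phi_prev - a * phi_prev[::-1]
        phi[-1] = a
        v *= 1.0 - a * a
        phi_prev = phi
    return pac


def select_trend_df(
    y: np.ndarray,
    make_design: Callable[[int], np.ndarray],
    candidate_df_per_year: Sequence[int],
    pacf_max_lag: int = 52,
    residual_type: str = "deviance",
) -> tuple[int, dict[int, float]]:
    """Choose the trend-spline df/year minimising the summed absolute PACF.

    Refits the model returned by ``make_design(df_per_year)`` for every
    candidate, computes the residual PACF over lags ``1..pacf_max_lag`` and
    returns the candidate with the smallest criterion (ties break toward
    smaller df).  Also returns the per-candidate criterion values.
    """
    if not candidate_df_per_year:
        raise ValueError("need at least one candidate df")
    cands = sorted(candidate_df_per_year)
    if len(cands) == 1:
        return cands[0], {}
    scores: dict[int, float] = {}
    for df in cands:
        try:
            fit = fit_quasipoisson(y, make_design(df))
        except (NonConvergenceError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"candidate trend df {df}/yr skipped: {exc}")
            continue
        res = (
            fit.deviance_residuals
            if residual_type == "deviance"
            else fit.pearson_residuals
        )
        scores[df] = float(np.sum(np.abs(pacf(res, pacf_max_lag))))
    if not scores:
        raise NonConvergenceError("all candidate trend-df fits failed")
    best = min(scores, key=lambda d: (scores[d], d))
    return best, scores
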