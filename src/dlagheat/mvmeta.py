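"""Stage two: intercept-only multivariate random-effects meta-analysis.

District-level reduced coefficient vectors ``y_i`` with within-district
covariances ``S_i`` are pooled under the model

    y_i ~ Normal(mu, S_i + Psi)

where ``Psi`` is the between-district covariance, estimated by restricted
maximum likelihood (REML) with ``Psi`` parameterised through its Cholesky
factor so positive semi-definiteness holds by construction.  Heterogeneity
is summarised by the Cochran Q statistic under fixed-effects weights and
``I^2 = max(0, (Q - df) / Q) * 100``.  Best linear unbiased predictions
(BLUPs) shrink each district's estimate toward the pooled mean in
proportion to the within- versus between-district covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .crossbasis import ReducedCurve


@dataclass
class MetaResult:
    mu: np.ndarray  # (vx,)
    mu_vcov: np.ndarray  # (vx, vx)
    psi: np.ndarray  # (vx, vx)
    blups: list[np.ndarray]
    blup_vcovs: list[np.ndarray]
    q: float
    q_df: int
    i2: float
    method: str
    converged: bool
    neg2_reml: float


def _stack(curves: list[ReducedCurve]) -> tuple[np.ndarray, list[np.ndarray]]:
    vx = len(curves[0].eta)
    for i, c in enumerate(curves):
        if len(c.eta) != vx:
            raise ValueError(f"curve {i} has dimension {len(c.eta)}, expected {vx}")
    ys = np.array([c.eta for c in curves])
    Ss = [np.asarray(c.sigma, dtype=float) for c in curves]
    for i, S in enumerate(Ss):
        try:
            np.linalg.cholesky(S + 1e-12 * np.trace(S) / len(S) * np.eye(len(S)))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"within covariance of curve {i} is singular") from exc
    return ys, Ss


def _gls_mu(ys: np.ndarray, Ss: list[np.ndarray], psi: np.ndarray):
    Ws = [np.linalg.inv(S + psi) for S in Ss]
    U = np.sum(Ws, axis=0)
    Uinv = np.linalg.inv(U)
    mu = Uinv @ np.sum([W @ y for W, y in zip(Ws, ys)], axis=0)
    return mu, Uinv, Ws, U


def _neg2_reml(params: np.ndarray, ys: np.ndarray, Ss: list[np.ndarray],
               vx: int, restricted: bool) -> float:
    L = np.zeros((vx, vx))
    L[np.tril_indices(vx)] = params
    psi = L @ L.T
    try:
        mu, _, Ws, U = _gls_mu(ys, Ss, psi)
    except np.linalg.LinAlgError:
        return 1e12
    val = 0.0
    for y, S, W in zip(ys, Ss, Ws):
        sign, logdet = np.linalg.slogdet(S + psi)
        if sign <= 0:
            return 1e12
        r = y - mu
        val += logdet + r @ W @ r
    if restricted:
        sign, logdet = np.linalg.slogdet(U)
        if sign <= 0:
            return 1e12
        val += logdet
    return float(val)


def _mom_psi(ys: np.ndarray, Ss: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments start/fallback: sample scatter minus mean S, PSD part."""
    k, vx = ys.shape
    if k < 2:
        return np.zeros((vx, vx))
    scatter = np.cov(ys.T, bias=False).reshape(vx, vx)
    raw = scatter - np.mean(Ss, axis=0)
    w, v = np.linalg.eigh((raw + raw.T) / 2)
    return (v * np.maximum(w, 0.0)) @ v.T


def meta_fit(curves: list[ReducedCurve], method: str = "reml") -> MetaResult:
    """Pool reduced curves with an intercept-only meta-regression.

    ``method`` is one of ``reml`` (default), ``ml`` or ``fixed`` (forces
    ``Psi = 0``).  A single curve returns itself with zero heterogeneity.
    """
    if not curves:
        raise ValueError("need at least one curve")
    ys, Ss = _stack(curves)
    k, vx = ys.shape

    if k == 1:
        return MetaResult(
            mu=ys[0].copy(), mu_vcov=Ss[0].copy(), psi=np.zeros((vx, vx)),
            blups=[ys[0].copy()], blup_vcovs=[Ss[0].copy()],
            q=0.0, q_df=0, i2=0.0, method=method, converged=True, neg2_reml=np.nan,
        )

    converged = True
    neg2 = np.nan
    if method == "fixed":
        psi = np.zeros((vx, vx))
    else:
        restricted = method == "reml"
        psi0 = _mom_psi(ys, Ss)
        # start on/near the MoM solution; jitter keeps the Cholesky defined
        L0 = np.linalg.cholesky(psi0 + 1e-6 * np.mean([np.trace(S) for S in Ss]) / vx * np.eye(vx))
        x0 = L0[np.tril_indices(vx)]
        res = optimize.minimize(
            _neg2_reml, x0, args=(ys, Ss, vx, restricted),
            method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        res = optimize.minimize(
            _neg2_reml, res.x, args=(ys, Ss, vx, restricted), method="BFGS",
            options={"gtol": 1e-7, "maxiter": 500},
        )
        if not np.isfinite(res.fun):
            warnings.warn("meta-analysis likelihood optimisation failed; "
                          "falling back to method-of-moments Psi")
            psi = psi0
            converged = False
        else:
            L = np.zeros((vx, vx))
            L[np.tril_indices(vx)] = res.x
            psi = L @ L.T
            neg2 = float(res.fun)
            converged = True

    mu, mu_vcov, _, _ = _gls_mu(ys, Ss, psi)

    # fixed-effects Q: weights ignore Psi by convention
    mu_fe, _, W_fe, _ = _gls_mu(ys, Ss, np.zeros((vx, vx)))
    q = float(sum((y - mu_fe) @ W @ (y - mu_fe) for y, W in zip(ys, W_fe)))
    q_df = (k - 1) * vx
    i2 = float(max(0.0, (q - q_df) / q) * 100.0) if q > 0 else 0.0

    blups, blup_vcovs = _blups(ys, Ss, mu, mu_vcov, psi)
    return MetaResult(
        mu=mu, mu_vcov=mu_vcov, psi=psi, blups=blups, blup_vcovs=blup_vcovs,
        q=q, q_df=q_df, i2=i2, method=method, converged=converged, neg2_reml=neg2,
    )


def _blups(ys, Ss, mu, mu_vcov, psi):
    blups, vcovs = [], []
    for y, S in zip(ys, Ss):
        G = psi @ np.linalg.inv(S + psi)  # shrinkage toward mu as psi -> 0
        b = mu + G @ (y - mu)
        A = np.eye(len(mu)) - G
        cov = psi - G @ psi + A @ mu_vcov @ A.T
        vcovs.append((cov + cov.T) / 2)
        blups.append(b)
    return blups, vcovs


def blup_curves(result: MetaResult, curves: list[ReducedCurve]) -> list[ReducedCurve]:
    """Per-district BLUP curves on the same exposure basis as the inputs."""
    if len(result.blups) != len(curves):
        raise ValueError("result and curves length mismatch")
    return [
        ReducedCurve(
            eta=b, sigma=v,
            exposure_spec=c.exposure_spec, temp_range=c.temp_range,
        )
        for b, v, c in zip(result.blups, result.blup_vcovs, curves)
    ]


def pooled_curve(result: MetaResult, template: ReducedCurve,
                 temp_range: tuple[float, float] | None = None) -> ReducedCurve:
    """Pooled-mean curve on the exposure basis of ``template``."""
    return ReducedCurve(
        eta=result.mu, sigma=result.mu_vcov,
        exposure_spec=template.exposure_spec,
        temp_range=temp_range if temp_range is not None else template.temp_range,
    )
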