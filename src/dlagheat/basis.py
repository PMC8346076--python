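"""Natural cubic spline bases and the knot-placement rules used by the model.

Two knot rules appear throughout the analysis: exposure knots at empirical
percentiles of the observed temperature distribution, and lag knots equally
spaced on the log scale of the lag axis.  The spline itself is the classic
natural cubic B-spline: cubic and twice continuously differentiable inside
the boundary knots, constrained to be linear beyond them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineSpec:
    """Definition of a natural cubic spline basis.

    Parameters
    ----------
    knots : array-like
        Internal knots, strictly increasing, strictly inside ``boundary``.
    boundary : (float, float)
        Boundary knots; the basis is linear outside this interval.
    intercept : bool
        Whether the basis spans the constant function.  The column count
        (degrees of freedom) is ``len(knots) + 1 + intercept``.
    """

    knots: tuple[float, ...]
    boundary: tuple[float, float]
    intercept: bool = False
    kind: str = field(default="natural_cubic")

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in np.atleast_1d(np.asarray(self.knots, dtype=float)))
        object.__setattr__(self, "knots", knots)
        lo, hi = float(self.boundary[0]), float(self.boundary[1])
        object.__setattr__(self, "boundary", (lo, hi))
        if not lo < hi:
            raise ValueError(f"boundary must be increasing, got {self.boundary}")
        arr = np.asarray(knots)
        if arr.size and (np.any(np.diff(arr) <= 0) or arr.min() <= lo or arr.max() >= hi):
            raise ValueError(
                "internal knots must be strictly increasing and strictly inside "
                f"the boundary {self.boundary}; got {knots}"
            )
        if self.kind != "natural_cubic":
            raise ValueError(f"unsupported spline kind {self.kind!r}")

    @property
    def df(self) -> int:
        return len(self.knots) + 1 + int(self.intercept)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "knots": list(self.knots),
            "boundary": list(self.boundary),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            knots=tuple(d["knots"]),
            boundary=tuple(d["boundary"]),
            intercept=bool(d.get("intercept", False)),
            kind=d.get("kind", "natural_cubic"),
        )


@dataclass(frozen=True)
class BasisMatrix:
    """A spline basis evaluated at a set of abscissae."""

    values: np.ndarray  # (n, df)
    spec: SplineSpec
    x: np.ndarray


def knots_by_percentile(x: np.ndarray, percentiles) -> np.ndarray:
    """Empirical percentiles of ``x`` used as internal knots.

    Uses the linear-interpolation definition of the empirical percentile
    (``numpy.percentile`` default).  Raises if the resulting knots are not
    strictly increasing (e.g. heavily tied data).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("x must be non-empty")
    pcts = np.asarray(percentiles, dtype=float)
    if np.any((pcts <= 0) | (pcts >= 100)):
        raise ValueError("percentiles must lie strictly in (0, 100)")
    if np.any(np.diff(pcts) <= 0):
        raise ValueError("percentiles must be strictly increasing")
    knots = np.percentile(x, pcts)
    if np.any(np.diff(knots) <= 0) or knots.size and (
        knots.min() <= x.min() or knots.max() >= x.max()
    ):
        raise ValueError(
            "percentile knots are duplicated or fall on the data range "
            "boundary; use fewer knots or more spread-out percentiles"
        )
    return knots


def log_lag_knots(max_lag: int, n_knots: int) -> np.ndarray:
    """Internal lag knots equally spaced on the log scale of ``[1, max_lag]``.

    Returns ``exp(k * log(L) / (n_knots + 1))`` for ``k = 1..n_knots``, i.e.
    a geometric progression strictly inside ``(1, L)``.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n_knots < 0:
        raise ValueError("n_knots must be >= 0")
    if n_knots == 0:
        return np.empty(0)
    k = np.arange(1, n_knots + 1)
    return np.exp(k * np.log(max_lag) / (n_knots + 1))


def _bspline_design(x: np.ndarray, aug_knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Cubic B-spline design matrix (and derivatives) on an augmented knot vector."""
    nb = len(aug_knots) - 4
    out = np.empty((len(x), nb))
    for i in range(nb):
        c = np.zeros(nb)
        c[i] = 1.0
        sp = BSpline(aug_knots, c, 3, extrapolate=True)
        if deriv:
            sp = sp.derivative(deriv)
        out[:, i] = sp(x)
    return out


def _natural_transform(spec: SplineSpec) -> tuple[np.ndarray, np.ndarray]:
    """Augmented knots and the projection enforcing the natural constraints.

    The cubic B-spline basis on the augmented knot vector is projected onto
    the null space of the second-derivative constraints at the two boundary
    knots (QR construction).  When ``intercept`` is false the first B-spline
    column is dropped before projecting, so the returned basis together with
    a model intercept spans the full natural-spline space.
    """
    lo, hi = spec.boundary
    aug = np.concatenate([[lo] * 4, np.asarray(spec.knots), [hi] * 4])
    const = _bspline_design(np.array([lo, hi]), aug, deriv=2)
    keep = slice(None) if spec.intercept else slice(1, None)
    const = const[:, keep]
    q, _ = np.linalg.qr(const.T, mode="complete")
    h = q[:, 2:]
    return aug, (keep, h)


def ns_eval(x: np.ndarray, spec: SplineSpec) -> BasisMatrix:
    """Evaluate the natural cubic spline basis at ``x``.

    Inside the boundary the basis is the constrained cubic B-spline basis;
    outside it is extended linearly from the boundary value and slope.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    lo, hi = spec.boundary
    aug, (keep, h) = _natural_transform(spec)

    xin = np.clip(x, lo, hi)
    vals = _bspline_design(xin, aug)[:, keep] @ h

    below = x < lo
    above = x > hi
    if below.any() or above.any():
        bpts = np.array([lo, hi])
        b0 = _bspline_design(bpts, aug)[:, keep] @ h
        b1 = _bspline_design(bpts, aug, deriv=1)[:, keep] @ h
        if below.any():
            vals[below] = b0[0] + np.outer(x[below] - lo, b1[0])
        if above.any():
            vals[above] = b0[1] + np.outer(x[above] - hi, b1[1])

    assert vals.shape[1] == spec.df
    return BasisMatrix(values=vals, spec=spec, x=x)


def trend_spline_spec(n_weeks: int, df: int) -> SplineSpec:
    """Spline of the week index controlling seasonality and long-term trend.

    ``df`` total degrees of freedom (no intercept); internal knots at equal
    quantiles of the week index ``0..n_weeks-1``.
    """
    if df < 1:
        raise ValueError("trend df must be >= 1")
    n_internal = df - 1
    qs = np.linspace(0, 100, n_internal + 2)[1:-1]
    knots = np.percentile(np.arange(n_weeks, dtype=float), qs) if n_internal else ()
    return SplineSpec(knots=tuple(np.atleast_1d(knots)), boundary=(0.0, float(n_weeks - 1)))
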