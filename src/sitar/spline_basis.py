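"""Natural cubic B-spline basis with knots at data quantiles.

The mean growth curve is a natural cubic spline: a cubic B-spline
constrained to be linear beyond its boundary knots.  The basis here spans
the full natural-spline space (constants included), with ``df`` columns and
``df - 2`` interior knots placed at equally spaced quantiles of the
fitting-scale ages.  First and second derivatives are analytic, which the
velocity curves and the curvature terms of the mixed-model Hessian rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "SplineSpec",
    "knots_from_quantiles",
    "natural_basis",
    "natural_basis_deriv",
    "natural_basis_deriv2",
]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a natural cubic spline on the fitting (transformed-age) scale.

    ``df`` counts basis columns; the spanned space includes constants, and
    the number of interior knots is ``df - 2``.
    """

    df: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        a, b = self.boundary_knots
        if not a < b:
            raise ValueError(f"boundary knots must be increasing, got {self.boundary_knots}")
        ik = np.asarray(self.interior_knots, dtype=float)
        if len(ik) != self.df - 2:
            raise ValueError(
                f"df={self.df} requires {self.df - 2} interior knots, got {len(ik)}"
            )
        if len(ik) and (np.any(np.diff(ik) <= 0) or ik[0] <= a or ik[-1] >= b):
            raise ValueError(
                "interior knots must be strictly increasing and strictly inside "
                f"({a}, {b}); got {self.interior_knots}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "df": self.df,
                "interior_knots": list(self.interior_knots),
                "boundary_knots": list(self.boundary_knots),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplineSpec":
        d = json.loads(text)
        return cls(
            df=d["df"],
            interior_knots=tuple(d["interior_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
        )


def knots_from_quantiles(x, df: int) -> SplineSpec:
    """Place boundary knots at the range of ``x`` and ``df - 2`` interior knots
    at the ``k/(df-1)`` quantiles (type-7, linear interpolation), ``k = 1..df-2``.
    """
    x = np.asarray(x, dtype=float)
    if df < 3:
        raise ValueError(f"df must be >= 3, got {df}")
    distinct = np.unique(x)
    if distinct.size < df:
        raise ValueError(
            f"need at least {df} distinct ages for df={df}, got {distinct.size}"
        )
    probs = np.arange(1, df - 1) / (df - 1)
    interior = np.quantile(x, probs)  # numpy default is the type-7 estimator
    spec = SplineSpec(
        df=df,
        interior_knots=tuple(float(k) for k in interior),
        boundary_knots=(float(distinct[0]), float(distinct[-1])),
    )
    return spec


def _full_knots(spec: SplineSpec) -> np.ndarray:
    a, b = spec.boundary_knots
    return np.concatenate([[a] * 4, spec.interior_knots, [b] * 4])


@lru_cache(maxsize=64)
def _natural_map(spec: SplineSpec) -> np.ndarray:
    """(df+2) x df map from the unconstrained cubic B-spline coefficients to the
    natural subspace (zero second derivative at both boundary knots)."""
    t = _full_knots(spec)
    k = len(t) - 4  # number of unconstrained B-splines = df + 2
    bs = BSpline(t, np.eye(k), 3, extrapolate=True)
    constraints = bs.derivative(2)(np.array(spec.boundary_knots))  # (2, k)
    nmap = null_space(constraints)
    if nmap.shape[1] != spec.df:
        raise RuntimeError("natural constraint rank unexpected")  # pragma: no cover
    return nmap


@lru_cache(maxsize=64)
def _evaluators(spec: SplineSpec):
    """Cached natural-basis BSpline objects for derivative orders 0..2."""
    t = _full_knots(spec)
    nmap = _natural_map(spec)
    base = BSpline(t, nmap, 3, extrapolate=True)
    return base, base.derivative(1), base.derivative(2)


def _eval(x, spec: SplineSpec, deriv: int) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    bs_all = _evaluators(spec)
    bs = bs_all[deriv]
    a, b = spec.boundary_knots
    out = np.empty((x.size, spec.df))
    inside = (x >= a) & (x <= b)
    if inside.any():
        out[inside] = bs(x[inside])
    # the natural spline is linear beyond the boundary knots: extend by hand
    val, der, _ = bs_all
    for mask, edge in ((x < a, a), (x > b, b)):
        if not mask.any():
            continue
        v0 = val(np.array([edge]))[0]
        v1 = der(np.array([edge]))[0]
        if deriv == 0:
            out[mask] = v0 + np.outer(x[mask] - edge, v1)
        elif deriv == 1:
            out[mask] = v1
        else:
            out[mask] = 0.0
    return out


def natural_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis: ``len(x) x df`` matrix.

    Beyond the boundary knots the basis continues linearly, by construction
    of the natural constraints.
    """
    return _eval(x, spec, 0)


def natural_basis_deriv(x, spec: SplineSpec) -> np.ndarray:
    """First derivative of :func:`natural_basis` with respect to ``x``."""
    return _eval(x, spec, 1)


def natural_basis_deriv2(x, spec: SplineSpec) -> np.ndarray:
    """Second derivative of :func:`natural_basis`; zero at and beyond boundaries."""
    return _eval(x, spec, 2)
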