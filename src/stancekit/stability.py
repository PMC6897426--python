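"""Stability charts for delayed proportional-derivative balance control.

The closed loop ``theta'' = theta/tau_mech^2 - p*theta(t-tau) - d*thetadot(t-tau)``
has the transcendental characteristic equation

    lambda^2 - 1/tau_mech^2 + (p + d*lambda) * exp(-tau*lambda) = 0.

In the dimensionless gains ``P = p*tau_delay^2``, ``D = d*tau_delay`` and the
relative speed ``S = tau_delay/tau_mech``, the stable region in the (P, D)
plane is bounded by two closed-form curves:

* the static (fold) boundary, the vertical line ``P = S^2`` below which the
  total restoring stiffness cannot hold up the weight, and
* the oscillatory (Hopf) boundary, the curve parametrised by ``x > 0``::

      P(x) = (x^2 + S^2) * cos(x)
      D(x) = (x^2 + S^2) * sin(x) / x

The stable region is the area enclosed between the static line and the first
arc of the parametric curve (x from 0 up to the arc's return to P = S^2).
It is non-empty only for ``S < sqrt(2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon

__all__ = [
    "S_MAX",
    "ControllerGains",
    "BoundarySample",
    "StabilityVerdict",
    "boundary_curve",
    "static_boundary",
    "stable_region_polygon",
    "is_stable",
]

#: Largest relative speed for which any delayed-PD gains are stabilizing.
S_MAX = math.sqrt(2.0)

# arc resolution for the region polygon; grid error is far below the
# membership tolerance of 1e-6 used in tests
_N_ARC = 2000


@dataclass(frozen=True)
class ControllerGains:
    """Per-inertia feedback gains of the delayed controller.

    ``p`` (1/s^2 per rad) and ``d`` (1/s per rad) are the proportional and
    derivative gains divided by the rotational inertia J; ``a`` is the
    dimensionless acceleration gain and ``i`` (1/s^3 per rad) the
    per-inertia integral gain.  The dimensionless counterparts are
    ``P = p*tau^2, D = d*tau, A = a, I = i*tau^3`` for delay ``tau``.
    """

    p: float = 0.0
    d: float = 0.0
    a: float = 0.0
    i: float = 0.0

    def dimensionless(self, tau_delay: float) -> tuple[float, float, float, float]:
        """Return (P, D, A, I) for the given delay."""
        return (
            self.p * tau_delay**2,
            self.d * tau_delay,
            self.a,
            self.i * tau_delay**3,
        )

    @classmethod
    def from_dimensionless(
        cls, P: float, D: float, tau_delay: float, A: float = 0.0, I: float = 0.0
    ) -> "ControllerGains":
        return cls(p=P / tau_delay**2, d=D / tau_delay, a=A, i=I / tau_delay**3)


@dataclass(frozen=True)
class BoundarySample:
    """One point of the oscillatory stability boundary."""

    x: float
    P: float
    D: float


@dataclass(frozen=True)
class StabilityVerdict:
    """Membership result with a distance-to-boundary diagnostic.

    ``margin`` is the euclidean distance in the (P, D) plane to the region
    boundary: positive inside the stable region, negative outside.
    """

    stable: bool
    margin: float

    def __bool__(self) -> bool:  # allows `if is_stable(...)`
        return self.stable


def _check_S(S: float) -> None:
    if S < 0:
        raise ValueError(f"relative speed S must be >= 0, got {S}")


def boundary_curve(S: float, x_grid) -> list[BoundarySample]:
    """Sample the oscillatory stability boundary at the given x > 0 values.

    The x -> 0+ limit of the curve is the point (S^2, S^2); request it via
    :func:`static_boundary` and the limit rather than x = 0.
    """
    _check_S(S)
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0):
        raise ValueError("boundary parameter x must be > 0 (the x->0 limit is (S^2, S^2))")
    r = x**2 + S**2
    P = r * np.cos(x)
    D = r * np.sin(x) / x
    return [BoundarySample(float(xi), float(Pi), float(Di)) for xi, Pi, Di in zip(x, P, D)]


def static_boundary(S: float) -> float:
    """Position of the static boundary line P = S^2.

    Gains with ``P < S^2`` cannot stabilize the system for any D: the total
    stiffness-like restoring torque is weaker than the toppling torque of
    weight.
    """
    _check_S(S)
    return S * S


def _arc_crossing(S: float) -> float:
    """First x > 0 at which the parametric arc returns to the line P = S^2.

    Written as ``x^2 cos x - S^2 (1 - cos x)`` to avoid the cancellation of
    ``(x^2 + S^2) cos x - S^2`` at small x; positive near 0 for S < sqrt(2).
    """
    f = lambda x: x * x * math.cos(x) - S * S * (1.0 - math.cos(x))
    lo = 1e-6
    # cos(x*) = S^2/(x*^2 + S^2) > 0, so the crossing is below pi/2 for
    # S > 0 and exactly at pi/2 for S = 0 (bracket slightly past it)
    hi = math.pi / 2 + 1e-9
    return brentq(f, lo, hi, xtol=1e-14)


def stable_region_polygon(S: float) -> Polygon:
    """Shapely polygon of the stable (P, D) region for relative speed S.

    Raises
    ------
    ValueError
        If ``S >= sqrt(2)``: no stabilizing PD gains exist (the critically
        damped root would not be negative).
    """
    _check_S(S)
    if S >= S_MAX:
        raise ValueError(
            f"no stabilizing PD gains exist for S = {S} >= sqrt(2) = {S_MAX:.6f}"
        )
    x_star = _arc_crossing(S)
    x = np.linspace(x_star / _N_ARC, x_star, _N_ARC)
    r = x**2 + S**2
    P = r * np.cos(x)
    D = r * np.sin(x) / x
    s2 = S * S
    # arc from near (S^2, S^2) out to its return to P = S^2, closed by the
    # static line segment back down to the corner (S^2, S^2)
    pts = [(s2, s2)] + list(zip(P, D))
    return Polygon(pts)


def is_stable(gains: ControllerGains, S: float, tau_delay: float = 1.0) -> StabilityVerdict:
    """Test whether delayed-PD gains stabilize a plant with relative speed S.

    Parameters
    ----------
    gains
        PD gains (``a`` and ``i`` must be zero: boundaries are derived for
        the pure PD loop).
    S
        Relative speed tau_delay/tau_mech, in [0, sqrt(2)).
    tau_delay
        Delay used to form the dimensionless gains from ``gains``; with the
        default 1.0 the fields ``p, d`` are read directly as ``P, D``.
    """
    if gains.a != 0.0 or gains.i != 0.0:
        raise ValueError("stability boundaries are defined for pure PD gains (a = i = 0)")
    region = stable_region_polygon(S)  # validates S
    P, D, _, _ = gains.dimensionless(tau_delay)
    pt = Point(P, D)
    inside = region.contains(pt)
    dist = pt.distance(region.exterior)
    return StabilityVerdict(stable=bool(inside), margin=dist if inside else -dist)
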