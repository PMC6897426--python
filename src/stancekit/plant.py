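"""Linearized single-inverted-pendulum mechanics of quiet stance.

The body is modelled as a single rigid segment pivoting about the ankles.
Linearizing the torque balance about the equilibrium ankle angle gives

    theta'' = theta / tau_mech**2,        tau_mech = sqrt(J / (m g L cos(Theta0) - k)),

so the uncontrolled body falls away from vertical with e-folding time
``tau_mech``.  Ankle stiffness ``k`` slows the fall; at the critical
stiffness ``K_crit = m g L cos(Theta0)`` the passive restoring torque
exactly cancels the torque of weight and the fall stops altogether.

All computation here is carried out in normalized units: angles are
dimensionless multiples of the perturbation amplitude, torques are divided
by the weight torque ``m g L cos(Theta0)``, and stiffness is expressed as
the fraction ``k_frac = k / K_crit`` of the critical value.  The single
dimensionless number governing the control problem is the relative speed

    S = tau_delay / tau_mech,

the number of mechanical e-folding times that elapse during the neural
response delay: a perturbation is amplified by ``exp(S)`` before feedback
can act.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_TAU_M0",
    "DEFAULT_TAU_DELAY",
    "PlantParams",
    "Perturbation",
    "from_anthropometrics",
    "free_fall",
    "amplification_factor",
]

#: Base mechanical time constant (s) for human-like anthropometry
#: (J = m L^2, L = 1 m, upright equilibrium): 1/sqrt(g) with g = 9.81 m/s^2.
DEFAULT_TAU_M0 = 1.0 / math.sqrt(9.81)

#: Minimal neural response delay (s) for ankle responses to stance perturbations.
DEFAULT_TAU_DELAY = 0.14


class OverCriticalStiffnessError(ValueError):
    """Ankle stiffness above the critical stiffness is not modelled."""


@dataclass(frozen=True)
class PlantParams:
    """Normalized plant parameters of the linearized inverted pendulum.

    Parameters
    ----------
    tau_m0
        Base mechanical time constant (s) at zero ankle stiffness,
        ``sqrt(J / (m g L cos(Theta0)))``.
    k_frac
        Ankle stiffness as a fraction of the critical stiffness, in [0, 1].
    d_mech
        Dimensionless mechanical damping ``D_M = tau_delay * d_M`` (>= 0).
    tau_delay
        Neural response delay (s), > 0.
    """

    tau_m0: float = DEFAULT_TAU_M0
    k_frac: float = 0.5
    d_mech: float = 0.0
    tau_delay: float = DEFAULT_TAU_DELAY

    def __post_init__(self) -> None:
        if not (self.tau_m0 > 0):
            raise ValueError(f"tau_m0 must be positive, got {self.tau_m0}")
        if not (0.0 <= self.k_frac <= 1.0):
            raise ValueError(f"k_frac must lie in [0, 1], got {self.k_frac}")
        if not (self.d_mech >= 0):
            raise ValueError(f"d_mech must be >= 0, got {self.d_mech}")
        if not (self.tau_delay > 0):
            raise ValueError(f"tau_delay must be positive, got {self.tau_delay}")

    @property
    def tau_mech(self) -> float:
        """Mechanical time constant (s); ``inf`` at critical stiffness."""
        if self.k_frac == 1.0:
            return math.inf
        return self.tau_m0 / math.sqrt(1.0 - self.k_frac)

    @property
    def inv_tau_mech_sq(self) -> float:
        """1/tau_mech^2 (1/s^2); continuous through k_frac = 1 (value 0)."""
        return (1.0 - self.k_frac) / self.tau_m0**2

    @property
    def S(self) -> float:
        """Relative speed ``tau_delay / tau_mech`` (0 at critical stiffness)."""
        return self.tau_delay * math.sqrt(1.0 - self.k_frac) / self.tau_m0

    def with_(self, **changes) -> "PlantParams":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class Perturbation:
    """Initial condition of a perturbation: angle offset and angular velocity.

    Angles are in normalized units (the perturbation amplitude is the unit);
    velocity is per second.
    """

    theta0: float = 1.0
    thetadot0: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta0) and math.isfinite(self.thetadot0)):
            raise ValueError("perturbation must be finite")


def from_anthropometrics(
    m: float,
    g: float,
    L: float,
    J: float,
    theta_eq: float = 0.0,
    k: float = 0.0,
    tau_delay: float = DEFAULT_TAU_DELAY,
) -> PlantParams:
    """Build normalized plant parameters from dimensional anthropometrics.

    Parameters
    ----------
    m, g, L, J
        Mass (kg), gravitational acceleration (m/s^2), CoM height (m) and
        rotational inertia about the ankles (kg m^2).
    theta_eq
        Equilibrium ankle angle Theta0 (rad), measured from vertical.
    k
        Dimensional ankle stiffness (N m/rad), 0 <= k <= K_crit.
    tau_delay
        Neural response delay (s).

    Returns
    -------
    PlantParams
        With ``tau_m0 = sqrt(J / (m g L cos(theta_eq)))`` and
        ``k_frac = k / K_crit`` where ``K_crit = m g L cos(theta_eq)``.
    """
    if m <= 0 or g <= 0 or L <= 0 or J <= 0:
        raise ValueError("m, g, L, J must all be positive")
    k_crit = m * g * L * math.cos(theta_eq)
    if k_crit <= 0:
        raise ValueError("m g L cos(theta_eq) must be positive")
    if k < 0:
        raise ValueError("stiffness k must be >= 0")
    if k > k_crit * (1 + 1e-12):
        raise OverCriticalStiffnessError(
            f"over-critical stiffness not modelled: k = {k} > K_crit = {k_crit}"
        )
    return PlantParams(
        tau_m0=math.sqrt(J / k_crit),
        k_frac=min(k / k_crit, 1.0),
        tau_delay=tau_delay,
    )


def free_fall(params: PlantParams, pert: Perturbation, t) -> tuple:
    """Uncontrolled response during the neural delay (zero feedback torque).

    Solves ``theta'' = theta / tau_mech**2`` from ``(theta0, thetadot0)``:

        theta(t) = (theta0 + tau_mech*thetadot0)/2 * exp(+t/tau_mech)
                 + (theta0 - tau_mech*thetadot0)/2 * exp(-t/tau_mech)

    At critical stiffness (k_frac = 1) this degenerates to the drift
    ``theta(t) = theta0 + thetadot0 * t``.

    Accepts a scalar or array time ``t`` in ``[0, tau_delay]`` and returns
    ``(theta, thetadot)`` of matching shape.
    """
    import numpy as np

    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("free fall is defined for t >= 0 only")
    if params.k_frac == 1.0:
        theta = pert.theta0 + pert.thetadot0 * t
        thetadot = np.broadcast_to(np.float64(pert.thetadot0), t.shape).copy()
    else:
        tm = params.tau_mech
        a = 0.5 * (pert.theta0 + tm * pert.thetadot0)
        b = 0.5 * (pert.theta0 - tm * pert.thetadot0)
        ep, em = np.exp(t / tm), np.exp(-t / tm)
        theta = a * ep + b * em
        thetadot = (a * ep - b * em) / tm
    if theta.ndim == 0:
        return float(theta), float(thetadot)
    return theta, thetadot


def amplification_factor(params: PlantParams) -> float:
    """Factor ``exp(S)`` by which a perturbation grows during the delay.

    The growing mode of the free fall scales the initial condition by
    ``exp(tau_delay / tau_mech)`` by the time feedback first acts; equals 1
    at critical stiffness (S = 0).
    """
    return math.exp(params.S)
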