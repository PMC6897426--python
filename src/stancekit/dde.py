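"""Delay-differential-equation simulation of the closed balance loop.

Integrates

    theta'' = theta / tau_mech^2 - d_M theta'
              - p theta(t - tau) - d theta'(t - tau)
              - a theta''(t - tau) - i * integral_0^t theta(u - tau) du

by the method of steps: the delay tau is an exact multiple of the step, so
within each interval [k tau, (k+1) tau) every delayed quantity is a known,
already-computed history and a classical 4th-order Runge-Kutta step applies.
Half-step history lookups use 4-point Lagrange interpolation on the uniform
grid, with stencils clamped to the delay interval so that interpolation
never spans the contraction-onset kinks at multiples of tau.

The perturbation convention is an instantaneous unit angle offset at t = 0
with zero initial velocity and identically-zero pre-history, so the
controller output is zero until the first delayed feedback arrives at
t = tau.

Output torques are normalized to the weight torque m g L cos(Theta0):
the weight torque equals theta itself, the stiffness component of the
ground-reaction torque is k_frac * theta, and the contraction component is
tau_m0^2 times the per-inertia feedback law (since m g L cos(Theta0) =
J / tau_m0^2).  The centre of pressure traces the total ground-reaction
torque, stiffness + contraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plant import PlantParams, Perturbation, free_fall
from .stability import ControllerGains

__all__ = ["SimConfig", "SimResult", "simulate", "classify_response", "convergence_check"]

_DIVERGENCE_LIMIT = 1e6  # |theta| beyond which a run is flagged divergent

# centered 4-point Lagrange weights for a half-grid-step midpoint
_MID_W = np.array([-1.0, 9.0, 9.0, -1.0]) / 16.0


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    ``dt`` is an upper bound on the step; the integrator uses
    ``tau_delay / ceil(tau_delay / dt)`` so that delay multiples fall
    exactly on grid points.  ``None`` defaults to ``tau_delay / 200``.
    """

    dt: float | None = None
    horizon: float = 6.0
    perturbation: Perturbation = field(default_factory=Perturbation)
    controller_kind: str = "PD"

    def steps_per_delay(self, tau_delay: float) -> int:
        dt = self.dt if self.dt is not None else tau_delay / 200.0
        if dt > tau_delay / 100.0:
            raise ValueError(f"dt = {dt} too coarse: must be <= tau_delay/100")
        if self.horizon < 10.0 * tau_delay:
            raise ValueError(f"horizon = {self.horizon} must be >= 10*tau_delay")
        return int(math.ceil(tau_delay / dt))


@dataclass
class SimResult:
    """Time series and peak statistics of one closed-loop response.

    All torque traces are normalized to weight; ``torque_weight`` is theta
    itself and ``cop = torque_stiffness + torque_contraction`` pointwise.
    """

    t: np.ndarray
    theta: np.ndarray
    thetadot: np.ndarray
    torque_weight: np.ndarray
    torque_stiffness: np.ndarray
    torque_contraction: np.ndarray
    cop: np.ndarray
    peak_com: float
    peak_cop: float
    overshoot: float
    n_sign_changes: int
    diverged: bool
    params: PlantParams
    gains: ControllerGains
    config: SimConfig


def _lagrange_midpoint(arr: np.ndarray, x: float, lo: int, hi: int) -> float:
    """4-point Lagrange value of grid samples ``arr`` at fractional index x.

    The stencil is kept within grid indices [lo, hi] so the cubic never
    straddles a derivative kink at a delay-interval boundary.
    """
    j = int(math.floor(x))
    base = min(max(j - 1, lo), hi - 3)
    if base == j - 1:
        return float(_MID_W @ arr[base : base + 4])
    xs = x - base  # in stencil coordinates 0..3
    w0 = -(xs - 1) * (xs - 2) * (xs - 3) / 6.0
    w1 = xs * (xs - 2) * (xs - 3) / 2.0
    w2 = -xs * (xs - 1) * (xs - 3) / 2.0
    w3 = xs * (xs - 1) * (xs - 2) / 6.0
    a = arr[base : base + 4]
    return float(w0 * a[0] + w1 * a[1] + w2 * a[2] + w3 * a[3])


def simulate(
    params: PlantParams, gains: ControllerGains, config: SimConfig | None = None
) -> SimResult:
    """Integrate the delayed closed loop and decompose the torques.

    Unstable runs are not an error: integration stops once |theta| exceeds
    a divergence limit and the result is flagged, with peaks taken over the
    computed portion.
    """
    if config is None:
        config = SimConfig()
    tau = params.tau_delay
    n_per = config.steps_per_delay(tau)
    dt = tau / n_per
    n_int = int(math.ceil(config.horizon / tau))
    N = n_int * n_per
    t = np.arange(N + 1) * dt

    inv_tm2 = params.inv_tau_mech_sq
    d_mech_rate = params.d_mech / tau  # D_M = tau * d_M
    p, d, a, i_gain = gains.p, gains.d, gains.a, gains.i

    th = np.zeros(N + 1)
    thd = np.zeros(N + 1)
    thdd = np.zeros(N + 1)

    pert = config.perturbation
    th[0], thd[0] = pert.theta0, pert.thetadot0

    def delayed(arr: np.ndarray, step_x: float, k_interval: int) -> float:
        """History value at fractional grid index ``step_x`` (time x*dt - tau).

        Integrating interval ``k_interval`` reads history from the closed
        interval [(k-1) tau, k tau]; at the jump t = 0 the one-sided limit
        consistent with that interval is used (left limit 0 for the interval
        ending at the jump, right limit theta0 for the one starting there).
        """
        x = step_x - n_per
        if x < -1e-9:
            return 0.0  # zero pre-history
        if x < 1e-9:  # exactly the perturbation instant
            return float(arr[0]) if k_interval >= 1 else 0.0
        xi = int(round(x))
        if abs(x - xi) < 1e-9:
            return float(arr[xi])
        lo = max((k_interval - 1) * n_per, 0)
        hi = k_interval * n_per
        return _lagrange_midpoint(arr, x, lo, hi)

    def accel(k_interval, step_x, theta, thetad, z):
        th_d = delayed(th, step_x, k_interval)
        thd_d = delayed(thd, step_x, k_interval)
        out = inv_tm2 * theta - d_mech_rate * thetad - p * th_d - d * thd_d
        if a != 0.0:
            out -= a * delayed(thdd, step_x, k_interval)
        if i_gain != 0.0:
            out -= i_gain * z
        return out, th_d

    # state: theta, thetadot, z = integral of delayed theta from 0 to t
    y0, y1, y2 = pert.theta0, pert.thetadot0, 0.0
    thdd[0] = accel(0, 0.0, y0, y1, y2)[0]
    diverged = False
    k_stop = N
    # theta'' jumps at multiples of tau; the stored trace keeps the right
    # limit, but lookups from within an interval must see the left limit at
    # the interval's right edge.  thdd_left holds those one-sided values and
    # the boundary sample is patched while the interval is integrated.
    thdd_left = {0: 0.0}
    patched: tuple[int, float] | None = None
    for k in range(N):
        kint = k // n_per
        if a != 0.0 and k % n_per == 0:
            if patched is not None:
                thdd[patched[0]] = patched[1]
                patched = None
            if k in thdd_left:
                patched = (k, thdd[k])
                thdd[k] = thdd_left[k]
        x = float(k)
        f1, h1 = accel(kint, x, y0, y1, y2)
        b0 = y0 + 0.5 * dt * y1
        b1 = y1 + 0.5 * dt * f1
        b2 = y2 + 0.5 * dt * (h1 if i_gain != 0.0 else 0.0)
        f2, h2 = accel(kint, x + 0.5, b0, b1, b2)
        c0 = y0 + 0.5 * dt * b1
        c1 = y1 + 0.5 * dt * f2
        c2 = y2 + 0.5 * dt * (h2 if i_gain != 0.0 else 0.0)
        f3, h3 = accel(kint, x + 0.5, c0, c1, c2)
        d0 = y0 + dt * c1
        d1 = y1 + dt * f3
        d2 = y2 + dt * (h3 if i_gain != 0.0 else 0.0)
        f4, h4 = accel(kint, x + 1.0, d0, d1, d2)
        y0 = y0 + dt / 6.0 * (y1 + 2.0 * b1 + 2.0 * c1 + d1)
        y1 = y1 + dt / 6.0 * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
        if i_gain != 0.0:
            y2 = y2 + dt / 6.0 * (h1 + 2.0 * h2 + 2.0 * h3 + h4)
        th[k + 1], thd[k + 1] = y0, y1
        if a != 0.0 and (k + 1) % n_per == 0:
            # left limit first (needs the patched boundary still in place)
            thdd_left[k + 1] = accel(kint, x + 1.0, y0, y1, y2)[0]
            if patched is not None:
                thdd[patched[0]] = patched[1]
                patched = None
        thdd[k + 1] = accel((k + 1) // n_per, x + 1.0, y0, y1, y2)[0]
        if not (math.isfinite(y0) and math.isfinite(y1)) or abs(y0) > _DIVERGENCE_LIMIT:
            diverged = True
            k_stop = k + 1
            break
    if patched is not None:
        thdd[patched[0]] = patched[1]

    sl = slice(0, k_stop + 1)
    t, th, thd, thdd = t[sl], th[sl], thd[sl], thdd[sl]
    n = len(t)

    # delayed traces for the contraction torque (grid-aligned: exact lookups)
    th_del = np.zeros(n)
    thd_del = np.zeros(n)
    thdd_del = np.zeros(n)
    if n > n_per:
        th_del[n_per:] = th[: n - n_per]
        thd_del[n_per:] = thd[: n - n_per]
        thdd_del[n_per:] = thdd[: n - n_per]
    if i_gain != 0.0:
        z_trace = np.concatenate(([0.0], np.cumsum(0.5 * dt * (th_del[1:] + th_del[:-1]))))
    else:
        z_trace = np.zeros(n)
    contraction = params.tau_m0**2 * (
        p * th_del + d * thd_del + a * thdd_del + i_gain * z_trace
    )
    stiffness_torque = params.k_frac * th
    cop = stiffness_torque + contraction

    finite = np.isfinite(th)
    theta_f = th[finite]
    cop_f = cop[finite & np.isfinite(cop)]
    signs = np.sign(theta_f[np.abs(theta_f) > 1e-12])
    n_cross = int(np.sum(signs[1:] != signs[:-1])) if len(signs) > 1 else 0

    return SimResult(
        t=t,
        theta=th,
        thetadot=thd,
        torque_weight=th.copy(),
        torque_stiffness=stiffness_torque,
        torque_contraction=contraction,
        cop=cop,
        peak_com=float(np.max(theta_f)),
        peak_cop=float(np.max(cop_f)) if len(cop_f) else math.nan,
        overshoot=float(np.min(theta_f)),
        n_sign_changes=n_cross,
        diverged=diverged,
        params=params,
        gains=gains,
        config=config,
    )


def _settling_time(result: SimResult, tol: float) -> float:
    """Last time at which |theta| exceeds tol (0 if it never does)."""
    above = np.abs(result.theta) > tol
    if not above.any():
        return 0.0
    return float(result.t[np.where(above)[0][-1]])


def classify_response(result: SimResult, tol: float = 1e-3) -> str:
    """Label a simulated response.

    Returns one of ``unstable`` (|theta| grew beyond 10x its initial value),
    ``oscillatory`` (theta crosses zero more than once beyond ``tol``),
    ``sluggish`` (settling time more than 3x that of the critically damped
    response at the same plant), or ``critical-like``.
    """
    theta0 = abs(result.theta[0]) if result.theta[0] != 0 else 1.0
    if result.diverged or np.nanmax(np.abs(result.theta)) > 10.0 * theta0:
        return "unstable"
    big = result.theta[np.abs(result.theta) > tol]
    signs = np.sign(big)
    crossings = int(np.sum(signs[1:] != signs[:-1])) if len(signs) > 1 else 0
    if crossings > 1:
        return "oscillatory"
    # compare settling against the critically damped loop at the same plant
    from .criticality import pd_critical

    crit = pd_critical(result.params.S, result.params.tau_delay)
    ref = simulate(result.params, crit.gains, result.config)
    if _settling_time(result, tol) > 3.0 * _settling_time(ref, tol):
        return "sluggish"
    return "critical-like"


def convergence_check(
    params: PlantParams, gains: ControllerGains, config: SimConfig | None = None
) -> float:
    """Grid-halving self-convergence estimate: max |theta(dt) - theta(dt/2)|.

    The coarse grid points are a subset of the fine grid, so the traces are
    compared directly at the coarse times.
    """
    if config is None:
        config = SimConfig()
    coarse = simulate(params, gains, config)
    n_per = config.steps_per_delay(params.tau_delay)
    fine_cfg = SimConfig(
        dt=params.tau_delay / (2 * n_per),
        horizon=config.horizon,
        perturbation=config.perturbation,
        controller_kind=config.controller_kind,
    )
    fine = simulate(params, gains, fine_cfg)
    if coarse.diverged or fine.diverged:
        raise ArithmeticError("convergence check requires a stable configuration")
    n = len(coarse.theta)
    err = float(np.max(np.abs(coarse.theta - fine.theta[:: 2][:n])))
    if not math.isfinite(err):
        raise ArithmeticError("non-convergent refinement")
    return err
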