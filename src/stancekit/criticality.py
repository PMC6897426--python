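"""Generalized critical damping for delayed feedback controllers.

A second-order loop is critically damped when its characteristic polynomial
has a double negative root; that gain choice gives the fastest recovery from
a perturbation without oscillation.  For the delayed loop the characteristic
equation is transcendental, so the delay ``exp(-X)`` (X = tau_delay*lambda)
is replaced by a Pade rational approximant, turning the equation into a
polynomial of order n.  Criticality is then generalized to the polynomial
having a unique negative root ``-omega0`` of multiplicity n.  The recovery
time constant is ``tau_balance = tau_delay / omega0`` (the root lives in
delay-normalized time).

Four controller variants are supported:

* ``PD`` -- delayed proportional-derivative control; first-order Pade gives a
  cubic whose triple-root condition has the closed form
  ``omega0 = -2 + (16 - 4 S^2)^(1/3)``.
* ``PD_damped`` -- PD plus undelayed mechanical damping D_M; cubic solved
  numerically.
* ``PDA`` -- PD plus delayed acceleration feedback; second-order Pade gives a
  quartic.
* ``PID`` -- PD plus delayed integral feedback; first-order Pade gives a
  quartic.

All numeric solves are damped Newton iterations on the coefficient-matching
equations, seeded from the PD closed form; every returned solution is
verified by re-expanding ``(X + omega0)^n`` against the assembled
characteristic polynomial (the ``residual`` field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .plant import DEFAULT_TAU_M0
from .stability import S_MAX, ControllerGains

__all__ = [
    "CriticalSolution",
    "pd_critical",
    "pd_damped_critical",
    "pda_critical",
    "pid_critical",
    "stiffness_for_critical_p",
    "stiffness_for_constant_S",
    "characteristic_coeffs",
    "critical_residual",
]

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class CriticalSolution:
    """Critically damped gain set for one controller variant.

    Attributes
    ----------
    omega0
        Magnitude of the unique multiple root, in delay-normalized units
        (the root is ``X = -omega0`` with ``X = tau_delay * lambda``).
    gains
        Per-inertia critical gains.
    tau_balance
        Recovery time constant ``tau_delay / omega0`` in seconds.
    controller_kind
        One of ``PD``, ``PD_damped``, ``PDA``, ``PID``.
    residual
        Max absolute mismatch between the assembled characteristic
        polynomial and the expanded ``(X + omega0)^n``.
    """

    omega0: float
    gains: ControllerGains
    tau_balance: float
    controller_kind: str
    residual: float
    S: float
    tau_delay: float
    d_mech: float = 0.0

    @property
    def dimensionless(self) -> tuple[float, float, float, float]:
        """(P, D, A, I) at this solution's delay."""
        return self.gains.dimensionless(self.tau_delay)


# ---------------------------------------------------------------------------
# characteristic polynomials (descending powers of X) and the residual oracle


def characteristic_coeffs(
    kind: str, S: float, P: float, D: float, A: float = 0.0, I: float = 0.0,
    D_M: float = 0.0,
) -> np.ndarray:
    """Pade-approximated closed-loop characteristic polynomial, monic form."""
    s2 = S * S
    if kind == "PD":
        c = [1.0, 2.0 - D, 2.0 * D - P - s2, 2.0 * (P - s2)]
    elif kind == "PD_damped":
        c = [1.0, 2.0 - D + D_M, 2.0 * D + 2.0 * D_M - P - s2, 2.0 * (P - s2)]
    elif kind == "PDA":
        c = [
            1.0 + A,
            4.0 + D - 4.0 * A,
            8.0 - s2 + P - 4.0 * D + 8.0 * A,
            -4.0 * s2 - 4.0 * P + 8.0 * D,
            8.0 * (P - s2),
        ]
        return np.array(c) / (1.0 + A)
    elif kind == "PID":
        c = [1.0, 2.0 - D, 2.0 * D - s2 - P, 2.0 * P - 2.0 * s2 - I, 2.0 * I]
    else:
        raise ValueError(f"unknown controller kind {kind!r}")
    return np.array(c)


def critical_residual(sol: CriticalSolution) -> float:
    """Max |coefficient mismatch| between the polynomial and (X+omega0)^n."""
    P, D, A, I = sol.dimensionless
    coeffs = characteristic_coeffs(sol.controller_kind, sol.S, P, D, A, I, sol.d_mech)
    n = len(coeffs) - 1
    target = np.array([math.comb(n, k) * sol.omega0**k for k in range(n + 1)])
    return float(np.max(np.abs(coeffs - target)))


def _check_domain(S: float) -> None:
    if not (0.0 <= S < S_MAX):
        raise ValueError(
            f"omega0 <= 0: no critically damped solution for S = {S} "
            f"(requires 0 <= S < sqrt(2))"
        )


def _make_solution(kind, omega0, S, tau_delay, P, D, A=0.0, I=0.0, D_M=0.0):
    coeffs = characteristic_coeffs(kind, S, P, D, A, I, D_M)
    n = len(coeffs) - 1
    target = np.array([math.comb(n, k) * omega0**k for k in range(n + 1)])
    res = float(np.max(np.abs(coeffs - target)))
    if res > _RESIDUAL_TOL:
        raise ArithmeticError(
            f"{kind} critical solve did not reach a multiple root: residual {res:.3e}"
        )
    return CriticalSolution(
        omega0=omega0,
        gains=ControllerGains.from_dimensionless(P, D, tau_delay, A=A, I=I),
        tau_balance=tau_delay / omega0,
        controller_kind=kind,
        residual=res,
        S=S,
        tau_delay=tau_delay,
        d_mech=D_M,
    )


# ---------------------------------------------------------------------------
# PD: closed form


def pd_critical(S: float, tau_delay: float) -> CriticalSolution:
    """Closed-form triple-root gains of the delayed PD loop.

    The cubic ``X^3 + X^2(2-D) + X(2D-P-S^2) + 2(P-S^2)`` equals
    ``(X+omega0)^3`` exactly when::

        omega0 = -2 + (16 - 4 S^2)^(1/3)          (real cube-root branch)
        D_crit = 2 - 3*omega0 = 8 - 3 (16-4S^2)^(1/3)
        P_crit = 4 - S^2 + 6 (16-4S^2)^(1/3) - 3 (16-4S^2)^(2/3)

    ``omega0 > 0`` requires ``S < sqrt(2)``.
    """
    _check_domain(S)
    u = (16.0 - 4.0 * S * S) ** (1.0 / 3.0)
    omega0 = -2.0 + u
    D = 2.0 - 3.0 * omega0
    P = 4.0 - S * S + 6.0 * u - 3.0 * u * u
    return _make_solution("PD", omega0, S, tau_delay, P, D)


# ---------------------------------------------------------------------------
# damped Newton for the coefficient-matching systems


def _newton(f, x0, tol=1e-12, maxiter=200):
    """Damped Newton with numerical Jacobian and simple backtracking."""
    x = np.asarray(x0, dtype=float).copy()
    fx = f(x)
    for _ in range(maxiter):
        norm = np.max(np.abs(fx))
        if norm < tol:
            return x
        # forward-difference Jacobian
        n = len(x)
        J = np.empty((n, n))
        h = 1e-8 * np.maximum(1.0, np.abs(x))
        for j in range(n):
            xp = x.copy()
            xp[j] += h[j]
            J[:, j] = (f(xp) - fx) / h[j]
        try:
            step = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError as exc:
            raise ArithmeticError(f"singular Jacobian in Newton solve: {exc}") from exc
        # backtracking line search on the residual norm
        lam = 1.0
        for _ in range(40):
            xn = x + lam * step
            fn = f(xn)
            if np.max(np.abs(fn)) < norm:
                x, fx = xn, fn
                break
            lam *= 0.5
        else:
            raise ArithmeticError(
                f"Newton line search stalled, residual {norm:.3e}"
            )
    norm = np.max(np.abs(f(x)))
    if norm < tol:
        return x
    raise ArithmeticError(f"Newton did not converge: residual {norm:.3e}")


def pd_damped_critical(S: float, D_M: float, tau_delay: float) -> CriticalSolution:
    """Triple-root gains of the PD loop with undelayed mechanical damping.

    Solves for (omega0, P, D) the system::

        0 = omega0^3 - 2 (P - S^2)
        0 = 3 omega0^2 - (2D + 2 D_M - P - S^2)
        0 = 3 omega0 - (2 - D + D_M)

    reducing to :func:`pd_critical` at D_M = 0.
    """
    _check_domain(S)
    if D_M < 0:
        raise ValueError(f"mechanical damping D_M must be >= 0, got {D_M}")
    s2 = S * S

    def eqs(v):
        w, P, D = v
        return np.array(
            [
                w**3 - 2.0 * (P - s2),
                3.0 * w**2 - (2.0 * D + 2.0 * D_M - P - s2),
                3.0 * w - (2.0 - D + D_M),
            ]
        )

    seed = pd_critical(S, tau_delay)
    Ps, Ds, _, _ = seed.dimensionless
    w, P, D = _newton(eqs, [seed.omega0, Ps, Ds])
    if w <= 0:
        raise ValueError(
            f"no positive-omega0 critically damped solution for S={S}, D_M={D_M}"
        )
    return _make_solution("PD_damped", w, S, tau_delay, P, D, D_M=D_M)


def pda_critical(S: float, tau_delay: float) -> CriticalSolution:
    """Quadruple-root gains of the PD + delayed-acceleration loop.

    Uses the second-order Pade approximant
    ``exp(-X) ~ (X^2 - 4X + 8)/(X^2 + 4X + 8)`` and solves for
    (omega0, P, D, A) the system::

        0 = (1+A) 4 omega0   - (4 + D - 4A)
        0 = (1+A) 6 omega0^2 - (8 - S^2 + P - 4D + 8A)
        0 = (1+A) 4 omega0^3 - (-4 S^2 - 4P + 8D)
        0 = (1+A) omega0^4   - 8 (P - S^2)
    """
    _check_domain(S)
    s2 = S * S

    def eqs(v):
        w, P, D, A = v
        return np.array(
            [
                (1.0 + A) * 4.0 * w - (4.0 + D - 4.0 * A),
                (1.0 + A) * 6.0 * w**2 - (8.0 - s2 + P - 4.0 * D + 8.0 * A),
                (1.0 + A) * 4.0 * w**3 - (-4.0 * s2 - 4.0 * P + 8.0 * D),
                (1.0 + A) * w**4 - 8.0 * (P - s2),
            ]
        )

    seed = pd_critical(S, tau_delay)
    Ps, Ds, _, _ = seed.dimensionless
    w, P, D, A = _newton(eqs, [seed.omega0, Ps, Ds, 0.0])
    if w <= 0:
        raise ArithmeticError(f"PDA solve converged to non-positive omega0 = {w}")
    return _make_solution("PDA", w, S, tau_delay, P, D, A=A)


def pid_critical(S: float, tau_delay: float) -> CriticalSolution:
    """Quadruple-root gains of the PD + delayed-integral loop.

    First-order Pade on ``X^3 - S^2 X = -(P X + D X^2 + I) exp(-X)`` gives a
    quartic; solves for (omega0, P, D, I) the system::

        0 = 4 omega0   - (2 - D)
        0 = 6 omega0^2 - (2D - S^2 - P)
        0 = 4 omega0^3 - (2P - 2 S^2 - I)
        0 = omega0^4 - 2 I

    The returned branch is the one continuously connected to the PD solution
    as I -> 0; it always has I = omega0^4 / 2 >= 0.
    """
    _check_domain(S)
    s2 = S * S

    def eqs(v):
        w, P, D, I = v
        return np.array(
            [
                4.0 * w - (2.0 - D),
                6.0 * w**2 - (2.0 * D - s2 - P),
                4.0 * w**3 - (2.0 * P - 2.0 * s2 - I),
                w**4 - 2.0 * I,
            ]
        )

    seed = pd_critical(S, tau_delay)
    Ps, Ds, _, _ = seed.dimensionless
    w, P, D, I = _newton(eqs, [seed.omega0, Ps, Ds, seed.omega0**4 / 2.0])
    if w <= 0 or I < 0:
        raise ArithmeticError(
            f"PID solve left the physical branch (omega0={w}, I={I})"
        )
    return _make_solution("PID", w, S, tau_delay, P, D, I=I)


# ---------------------------------------------------------------------------
# co-adaptation strategy solvers


def _S_of_kfrac(k_frac: float, tau_delay: float, tau_m0: float) -> float:
    return tau_delay * math.sqrt(1.0 - k_frac) / tau_m0


def stiffness_for_critical_p(
    p_target: float, tau_delay: float, tau_m0: float = DEFAULT_TAU_M0
) -> float:
    """Stiffness fraction at which ``p_target`` is the critical gain.

    The critical per-inertia proportional gain ``P_crit(S)/tau_delay^2`` is
    strictly decreasing in k_frac at fixed delay (S falls with stiffness and
    P_crit rises with S), so the inverse is found by bracketed root finding
    on k_frac in [0, 1).
    """

    def p_crit(kf: float) -> float:
        S = _S_of_kfrac(kf, tau_delay, tau_m0)
        sol = pd_critical(S, tau_delay)
        return sol.gains.p

    hi_kf = 1.0 - 1e-13
    p_max, p_min = p_crit(0.0), p_crit(hi_kf)
    if not (p_min <= p_target <= p_max):
        raise ValueError(
            f"p_target = {p_target} outside the achievable critical range "
            f"[{p_min:.6g}, {p_max:.6g}] at tau_delay = {tau_delay}"
        )
    return brentq(lambda kf: p_crit(kf) - p_target, 0.0, hi_kf, xtol=1e-13)


def stiffness_for_constant_S(
    tau_delay_new: float, S_target: float, tau_m0: float = DEFAULT_TAU_M0
) -> float:
    """Stiffness fraction keeping the relative speed S fixed at a new delay.

    Inverts ``S = tau_delay * sqrt(1 - k_frac) / tau_m0``:
    ``k_frac = 1 - (tau_m0 * S_target / tau_delay_new)^2``.  ``S_target = 0``
    is realized exactly by k_frac = 1 (critical stiffness).
    """
    if S_target < 0:
        raise ValueError(f"S_target must be >= 0, got {S_target}")
    if tau_delay_new <= 0:
        raise ValueError(f"tau_delay_new must be positive, got {tau_delay_new}")
    if S_target == 0.0:
        return 1.0
    tau_mech_needed = tau_delay_new / S_target
    if tau_mech_needed < tau_m0:
        raise ValueError(
            f"keeping S = {S_target} at tau_delay = {tau_delay_new} would need "
            f"tau_mech = {tau_mech_needed:.6g} s < tau_m0 = {tau_m0:.6g} s "
            "(negative stiffness)"
        )
    return 1.0 - (tau_m0 * S_target / tau_delay_new) ** 2
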