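"""Modal decomposition of multi-joint delayed-feedback systems.

A stance model with several joints (ankle, knee, hip, ...) obeys, after
linearization and normalization by the delay,

    tau_delay^2 * theta'' = M theta - C,

with ``M`` the (dimensionless) dynamics matrix and ``C`` the delayed
feedback torque vector.  In the generic case where ``M^T`` is
diagonalizable with real eigenvalues, projecting the state onto each left
eigenvector ``e_i`` (``M^T e_i = s_i e_i``) gives modal coordinates
``alpha_i = e_i . theta`` that evolve independently:

    tau_delay^2 * alpha_i'' = s_i alpha_i - e_i . C.

Each mode is thus a one-dimensional delayed balance problem with its own
relative speed ``S_i = sqrt(s_i)`` (for unstable, pendulum-like modes with
``s_i > 0``), and all single-joint machinery — stability charts, critical
gains — applies per mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .criticality import CriticalSolution, pd_critical
from .stability import S_MAX

__all__ = ["ModalSystem", "decompose", "modal_critical_gains"]

_EIG_RESIDUAL_TOL = 1e-10
_CONDITIONING_TOL = 1e-8  # smallest acceptable 1/cond of the eigenbasis
_IMAG_TOL = 1e-10


class NotDiagonalizableError(ValueError):
    """Dynamics matrix outside the generic real-diagonalizable case."""


@dataclass(frozen=True)
class ModalSystem:
    """Eigenstructure of the transposed dynamics matrix.

    ``mode_vectors`` has modes as rows (sorted by descending ``mode_values``,
    first nonzero component positive); ``mode_time_constants[i]`` is the
    mechanical time constant ``tau_i = tau_delay / sqrt(s_i)`` for unstable
    modes, NaN for modes with ``s_i <= 0`` (not pendulum-like: they do not
    topple and need no feedback in this framework).
    """

    dynamics_matrix: np.ndarray
    tau_delay: float
    mode_values: np.ndarray
    mode_vectors: np.ndarray
    mode_time_constants: np.ndarray
    conditioning: float

    @property
    def n_modes(self) -> int:
        return len(self.mode_values)

    @property
    def mode_speeds(self) -> np.ndarray:
        """Relative speed S_i = sqrt(s_i) per mode (0 for s_i <= 0)."""
        return np.sqrt(np.maximum(self.mode_values, 0.0))

    def project(self, theta: np.ndarray) -> np.ndarray:
        """Physical state -> modal coordinates alpha_i = e_i . theta."""
        return self.mode_vectors @ np.asarray(theta, dtype=float)

    def recombine(self, alpha: np.ndarray) -> np.ndarray:
        """Modal coordinates -> physical state (inverse of :meth:`project`)."""
        return np.linalg.solve(self.mode_vectors, np.asarray(alpha, dtype=float))


def decompose(matrix, tau_delay: float) -> ModalSystem:
    """Diagonalize the transposed dynamics matrix into independent modes.

    Raises :class:`NotDiagonalizableError` for complex eigenvalue pairs or
    an eigenbasis conditioned worse than 1e8 (near-defective matrix); the
    modal reduction is only valid in the generic diagonalizable case.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"dynamics matrix must be square, got shape {M.shape}")
    if tau_delay <= 0:
        raise ValueError("tau_delay must be positive")
    vals, vecs = np.linalg.eig(M.T)
    if np.max(np.abs(vals.imag)) > _IMAG_TOL * max(1.0, np.max(np.abs(vals))):
        raise NotDiagonalizableError(
            f"complex eigenvalue pair {vals[np.argmax(np.abs(vals.imag))]:.6g}: "
            "only real diagonalizable dynamics are handled"
        )
    vals = vals.real
    vecs = vecs.real
    cond = np.linalg.cond(vecs)
    if not np.isfinite(cond) or 1.0 / cond < _CONDITIONING_TOL:
        raise NotDiagonalizableError(
            f"eigenbasis conditioning {cond:.3e} exceeds 1e8: matrix is "
            "defective or too close to defective"
        )
    order = np.argsort(-vals)
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic sign: first nonzero component of each mode vector positive
    for j in range(vecs.shape[1]):
        nz = np.nonzero(np.abs(vecs[:, j]) > 1e-12)[0]
        if len(nz) and vecs[nz[0], j] < 0:
            vecs[:, j] = -vecs[:, j]
    vecs = vecs / np.linalg.norm(vecs, axis=0)
    residual = np.max(np.abs(M.T @ vecs - vecs * vals))
    if residual > _EIG_RESIDUAL_TOL * max(1.0, np.max(np.abs(M))):
        raise NotDiagonalizableError(f"eigenpair residual {residual:.3e} too large")
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_i = np.where(vals > 0, tau_delay / np.sqrt(np.maximum(vals, 0.0)), np.nan)
    return ModalSystem(
        dynamics_matrix=M,
        tau_delay=tau_delay,
        mode_values=vals,
        mode_vectors=vecs.T,  # rows are modes
        mode_time_constants=tau_i,
        conditioning=float(cond),
    )


def modal_critical_gains(
    system: ModalSystem,
) -> tuple[list[CriticalSolution], np.ndarray, np.ndarray]:
    """Per-mode critically damped PD gains and the physical gain matrices.

    Each unstable mode (``s_i > 0``) gets the one-dimensional critical
    solution at its own ``S_i``; stable modes (``s_i <= 0``) are treated as
    over-critically-stiff (S = 0).  Returns ``(solutions, K_p, K_d)`` where
    the dimensionless matrices act in the physical coordinates as
    ``C = K_p theta(t - tau) + K_d tau_delay thetadot(t - tau)``.
    """
    sols: list[CriticalSolution] = []
    P_diag = np.empty(system.n_modes)
    D_diag = np.empty(system.n_modes)
    for idx, (s_i, S_i) in enumerate(zip(system.mode_values, system.mode_speeds)):
        if S_i >= S_MAX:
            raise ValueError(
                f"mode {idx} (eigenvalue {s_i:.6g}) has S = {S_i:.6g} >= sqrt(2): "
                "no critically damped delayed-PD gains exist for it"
            )
        sol = pd_critical(float(S_i), system.tau_delay)
        sols.append(sol)
        P_diag[idx], D_diag[idx], _, _ = sol.dimensionless
    E = system.mode_vectors  # rows are e_i^T
    E_inv = np.linalg.inv(E)
    K_p = E_inv @ np.diag(P_diag) @ E
    K_d = E_inv @ np.diag(D_diag) @ E
    return sols, K_p, K_d
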