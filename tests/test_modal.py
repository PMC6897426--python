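import math

import numpy as np
import pytest

from stancekit import (
    PlantParams,
    SimConfig,
    decompose,
    modal_critical_gains,
    pd_critical,
    simulate,
)
from stancekit.criticality import critical_residual
from stancekit.modal import NotDiagonalizableError
from stancekit.stability import ControllerGains

TAU = 0.14


def coupled_dde_trace(M, Kp, Kd, tau, theta_init, n_per=100, horizon_delays=20):
    """Independent oracle: RK4 method-of-steps for the coupled vector loop
    tau^2 theta'' = M theta - Kp theta(t-tau) - Kd tau thetadot(t-tau),
    mirroring the jump convention of the scalar simulator (zero pre-history,
    angle offset at t = 0).
    """
    n = M.shape[0]
    N = horizon_delays * n_per
    dt = 1.0 / n_per  # delay-normalized time
    th = np.zeros((N + 1, n))
    thd = np.zeros((N + 1, n))
    th[0] = theta_init
    w = np.array([-1.0, 9.0, 9.0, -1.0]) / 16.0

    def hist(arr, x, kint):
        xi = x - n_per
        if xi < -1e-9:
            return np.zeros(n)
        i = int(round(xi))
        if abs(xi - i) < 1e-9:
            if i == 0 and kint == 0:
                return np.zeros(n)
            return arr[i]
        j = int(math.floor(xi))
        base = min(max(j - 1, max((kint - 1) * n_per, 0)), kint * n_per - 3)
        if base == j - 1:
            return w @ arr[base : base + 4]
        xs = xi - base
        lw = np.array(
            [
                -(xs - 1) * (xs - 2) * (xs - 3) / 6,
                xs * (xs - 2) * (xs - 3) / 2,
                -xs * (xs - 1) * (xs - 3) / 2,
                xs * (xs - 1) * (xs - 2) / 6,
            ]
        )
        return lw @ arr[base : base + 4]

    def f(x, y, yd, kint):
        return M @ y - Kp @ hist(th, x, kint) - Kd @ hist(thd, x, kint)

    for k in range(N):
        kint = k // n_per
        x = float(k)
        y, yd = th[k], thd[k]
        f1 = f(x, y, yd, kint)
        b1 = yd + 0.5 * dt * f1
        f2 = f(x + 0.5, y + 0.5 * dt * yd, b1, kint)
        c1 = yd + 0.5 * dt * f2
        f3 = f(x + 0.5, y + 0.5 * dt * b1, c1, kint)
        d1 = yd + dt * f3
        f4 = f(x + 1.0, y + dt * c1, d1, kint)
        th[k + 1] = y + dt / 6 * (yd + 2 * b1 + 2 * c1 + d1)
        thd[k + 1] = yd + dt / 6 * (f1 + 2 * f2 + 2 * f3 + f4)
    return th


def random_diagonalizable(rng, n):
    """Random matrix with positive eigenvalues of spread <= 10 and a
    well-conditioned real eigenbasis."""
    vals = np.sort(rng.uniform(0.2, 2.0, size=n))[::-1]
    while True:
        E = rng.normal(size=(n, n))
        if np.linalg.cond(E) < 20:
            break
    return np.linalg.solve(E, np.diag(vals) @ E), vals


class TestDecompose:
    def test_diagonal_matrix(self):
        sysm = decompose(np.diag([2.0, 0.5]), TAU)
        assert np.allclose(sysm.mode_values, [2.0, 0.5])
        assert np.allclose(np.abs(sysm.mode_vectors), np.eye(2))

    def test_symmetric_hand_example(self):
        sysm = decompose([[2.0, 1.0], [1.0, 2.0]], TAU)
        assert np.allclose(sysm.mode_values, [3.0, 1.0])
        r = 1 / math.sqrt(2)
        assert np.allclose(sysm.mode_vectors, [[r, r], [r, -r]])
        assert np.allclose(sysm.mode_speeds, [math.sqrt(3.0), 1.0])
        assert np.allclose(
            sysm.mode_time_constants, TAU / np.sqrt([3.0, 1.0])
        )

    def test_eigenpair_residual(self, rng):
        M, _ = random_diagonalizable(rng, 3)
        sysm = decompose(M, TAU)
        for e, s in zip(sysm.mode_vectors, sysm.mode_values):
            assert np.max(np.abs(M.T @ e - s * e)) < 1e-10

    def test_projection_recombination_roundtrip(self, rng):
        M, _ = random_diagonalizable(rng, 3)
        sysm = decompose(M, TAU)
        theta = rng.normal(size=3)
        assert np.allclose(sysm.recombine(sysm.project(theta)), theta, atol=1e-12)

    def test_complex_pair_rejected(self):
        with pytest.raises(NotDiagonalizableError, match="complex"):
            decompose([[0.0, -1.0], [1.0, 0.0]], TAU)

    def test_defective_matrix_rejected(self):
        with pytest.raises(NotDiagonalizableError):
            decompose([[1.0, 1.0], [0.0, 1.0]], TAU)  # Jordan block

    def test_stable_modes_flagged(self):
        sysm = decompose(np.diag([1.0, -0.5]), TAU)
        assert math.isnan(sysm.mode_time_constants[1])
        assert sysm.mode_speeds[1] == 0.0


class TestModalCriticalGains:
    def test_single_mode_reduces_to_scalar(self):
        sols, Kp, Kd = modal_critical_gains(decompose([[0.36]], TAU))
        scalar = pd_critical(0.6, TAU)
        assert sols[0].omega0 == pytest.approx(scalar.omega0, rel=1e-12)
        P, D, _, _ = scalar.dimensionless
        assert Kp[0, 0] == pytest.approx(P, rel=1e-12)
        assert Kd[0, 0] == pytest.approx(D, rel=1e-12)

    def test_degenerate_modes_share_solution(self):
        sols, Kp, Kd = modal_critical_gains(decompose(np.diag([0.49, 0.49]), TAU))
        assert sols[0].omega0 == sols[1].omega0
        P, D, _, _ = sols[0].dimensionless
        assert np.allclose(Kp, P * np.eye(2))
        assert np.allclose(Kd, D * np.eye(2))

    def test_per_mode_residual_oracle(self):
        sysm = decompose([[2.0, 1.0], [1.0, 2.0]], TAU)
        # sqrt(3) > sqrt(2): the fast mode is not stabilizable
        with pytest.raises(ValueError, match="mode 0"):
            modal_critical_gains(sysm)
        mild = decompose([[0.5, 0.25], [0.25, 0.5]], TAU)
        sols, _, _ = modal_critical_gains(mild)
        for sol in sols:
            assert critical_residual(sol) < 1e-10

    @pytest.mark.parametrize("n", [2, 3])
    def test_coupled_simulation_equals_modal_recombination(self, rng, n):
        """The coupled vector DDE under the recombined critical gain matrices
        equals the mode-wise recombination of independent scalar runs."""
        M, vals = random_diagonalizable(rng, n)
        sysm = decompose(M, TAU)
        sols, Kp, Kd = modal_critical_gains(sysm)

        theta_init = rng.uniform(0.5, 1.5, size=n)
        full = coupled_dde_trace(M, Kp, Kd, TAU, theta_init)

        # scalar runs per mode through the public simulator: a mode with
        # eigenvalue s behaves as a plant with tau_mech = tau/sqrt(s)
        alpha0 = sysm.project(theta_init)
        n_per, horizon_delays = 100, 20
        modal_traces = []
        for s_i, sol, a0 in zip(sysm.mode_values, sols, alpha0):
            plant = PlantParams(
                tau_m0=TAU / math.sqrt(s_i), k_frac=0.0, tau_delay=TAU
            )
            from stancekit import Perturbation

            cfg = SimConfig(
                dt=TAU / n_per,
                horizon=horizon_delays * TAU,
                perturbation=Perturbation(theta0=a0),
            )
            res = simulate(plant, sol.gains, cfg)
            modal_traces.append(res.theta)
        alpha = np.column_stack(modal_traces)
        recombined = np.array([sysm.recombine(a) for a in alpha])
        m = min(len(full), len(recombined))
        assert np.max(np.abs(full[:m] - recombined[:m])) < 1e-8
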