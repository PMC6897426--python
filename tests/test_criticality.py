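import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stancekit import (
    ControllerGains,
    PlantParams,
    is_stable,
    pd_critical,
    pd_damped_critical,
    pda_critical,
    pid_critical,
    stiffness_for_constant_S,
    stiffness_for_critical_p,
)
from stancekit.criticality import critical_residual

TAU_M0 = 1.0 / math.sqrt(9.81)

ALL_SOLVERS = [
    ("PD", lambda S, tau: pd_critical(S, tau)),
    ("PD_damped", lambda S, tau: pd_damped_critical(S, 0.25, tau)),
    ("PDA", lambda S, tau: pda_critical(S, tau)),
    ("PID", lambda S, tau: pid_critical(S, tau)),
]


class TestPdClosedForm:
    def test_reference_gains(self):
        """Half-critical stiffness, 0.14 s delay: the printed reference pair."""
        S = PlantParams(tau_m0=TAU_M0, k_frac=0.5, tau_delay=0.14).S
        sol = pd_critical(S, 0.14)
        assert round(sol.gains.p, 2) == 8.08
        assert round(sol.gains.d, 2) == 3.58

    def test_gains_after_20pct_delay_increase(self):
        S = PlantParams(tau_m0=TAU_M0, k_frac=0.5, tau_delay=0.168).S
        sol = pd_critical(S, 0.168)
        assert round(sol.gains.p, 2) == 6.99
        assert round(sol.gains.d, 2) == 3.15

    def test_triple_root_at_zero_speed(self):
        """omega0 = 16^(1/3) - 2 and the cubic is exactly (X + omega0)^3."""
        sol = pd_critical(0.0, 0.14)
        assert sol.omega0 == pytest.approx(16 ** (1 / 3) - 2, rel=1e-14)
        P, D, _, _ = sol.dimensionless
        cubic = np.array([1.0, 2 - D, 2 * D - P, 2 * P])
        expanded = np.array([1.0, 3 * sol.omega0, 3 * sol.omega0**2, sol.omega0**3])
        assert np.max(np.abs(cubic - expanded)) < 1e-12
        # the same cubic root-checked numerically: a genuine triple root
        roots = np.roots(cubic)
        assert np.allclose(roots, -sol.omega0, atol=1e-4)

    def test_domain_error_beyond_sqrt2(self):
        with pytest.raises(ValueError):
            pd_critical(math.sqrt(2), 0.14)

    def test_tau_balance_scale(self):
        sol = pd_critical(0.31, 0.14)
        assert sol.tau_balance == pytest.approx(0.14 / sol.omega0, rel=1e-14)


class TestResidualOracle:
    @pytest.mark.parametrize("kind,solver", ALL_SOLVERS)
    @pytest.mark.parametrize("S", np.linspace(0.0, 1.3, 14).tolist())
    def test_multiple_root_residual(self, kind, solver, S):
        """Expanding (X+omega0)^n reproduces every characteristic coefficient."""
        sol = solver(S, 0.14)
        assert sol.omega0 > 0
        assert critical_residual(sol) < 1e-10


class TestDampedVariant:
    def test_reduces_to_pd_without_damping(self):
        a = pd_critical(0.31, 0.14)
        b = pd_damped_critical(0.31, 0.0, 0.14)
        assert b.omega0 == pytest.approx(a.omega0, abs=1e-12)
        assert b.gains.p == pytest.approx(a.gains.p, abs=1e-10)
        assert b.gains.d == pytest.approx(a.gains.d, abs=1e-10)

    def test_mechanical_damping_speeds_recovery(self):
        assert (
            pd_damped_critical(0.31, 0.2, 0.14).tau_balance
            < pd_critical(0.31, 0.14).tau_balance
        )

    def test_negative_damping_rejected(self):
        with pytest.raises(ValueError):
            pd_damped_critical(0.31, -0.1, 0.14)


class TestPdaVariant:
    @pytest.mark.parametrize("S", [0.0, 0.31, 0.7, 1.0])
    def test_acceleration_feedback_speeds_recovery(self, S):
        assert pda_critical(S, 0.14).tau_balance < pd_critical(S, 0.14).tau_balance

    def test_needs_larger_pd_gains(self):
        pd = pd_critical(0.31, 0.14)
        pda = pda_critical(0.31, 0.14)
        assert pda.gains.p > pd.gains.p
        assert pda.gains.d > pd.gains.d


class TestPidVariant:
    @pytest.mark.parametrize("S", [0.0, 0.31, 0.7, 1.0])
    def test_integral_feedback_slows_recovery(self, S):
        assert pid_critical(S, 0.14).tau_balance > pd_critical(S, 0.14).tau_balance

    def test_integral_gain_branch(self):
        sol = pid_critical(0.31, 0.14)
        _, _, _, I = sol.dimensionless
        assert I == pytest.approx(sol.omega0**4 / 2, rel=1e-10)
        assert I >= 0


class TestMonotonicity:
    def test_critical_gains_fall_with_stiffness(self):
        kfs = np.linspace(0.0, 0.99, 15)
        sols = [
            pd_critical(PlantParams(k_frac=k, tau_delay=0.14).S, 0.14) for k in kfs
        ]
        p = [s.gains.p for s in sols]
        d = [s.gains.d for s in sols]
        tb = [s.tau_balance for s in sols]
        assert np.all(np.diff(p) < 0)
        assert np.all(np.diff(d) < 0)
        assert np.all(np.diff(tb) < 0)

    def test_critical_gains_fall_and_recovery_slows_with_delay(self):
        taus = np.linspace(0.14, 0.28, 15)
        sols = [
            pd_critical(PlantParams(k_frac=0.5, tau_delay=t).S, t) for t in taus
        ]
        assert np.all(np.diff([s.gains.p for s in sols]) < 0)
        assert np.all(np.diff([s.gains.d for s in sols]) < 0)
        assert np.all(np.diff([s.tau_balance for s in sols]) > 0)

    @pytest.mark.parametrize("S", np.linspace(0.0, 1.3, 8).tolist())
    def test_critical_gains_inside_stable_region(self, S):
        P, D, _, _ = pd_critical(S, 0.14).dimensionless
        assert is_stable(ControllerGains(p=P, d=D), S).stable

    @given(S=st.floats(0.0, 1.3), scale=st.floats(0.5, 4.0))
    @settings(max_examples=40, deadline=None)
    def test_dimensionless_gains_depend_only_on_S(self, S, scale):
        a = pd_critical(S, 0.14)
        b = pd_critical(S, 0.14 * scale)
        assert a.dimensionless == pytest.approx(b.dimensionless, rel=1e-12)


class TestCoAdaptationSolvers:
    def test_stiffness_making_reduced_gain_critical(self):
        kf = stiffness_for_critical_p(6.87, 0.14)
        assert kf == pytest.approx(0.6346, abs=2e-4)
        # round trip: critical p at that stiffness is the target
        S = PlantParams(k_frac=kf, tau_delay=0.14).S
        assert pd_critical(S, 0.14).gains.p == pytest.approx(6.87, abs=1e-9)

    def test_fixed_point(self):
        S = PlantParams(k_frac=0.5, tau_delay=0.14).S
        p_ref = pd_critical(S, 0.14).gains.p
        assert stiffness_for_critical_p(p_ref, 0.14) == pytest.approx(0.5, abs=1e-9)

    def test_table2_target(self):
        kf = stiffness_for_critical_p(5.61, 0.168)
        assert kf == pytest.approx(0.653, abs=1e-3)

    def test_out_of_range_reports_bounds(self):
        with pytest.raises(ValueError, match="achievable"):
            stiffness_for_critical_p(100.0, 0.14)

    def test_constant_S_stiffness(self):
        S_ref = PlantParams(k_frac=0.5, tau_delay=0.14).S
        kf = stiffness_for_constant_S(0.168, S_ref)
        assert kf == pytest.approx(0.6528, abs=1e-4)
        # invariance check: same S at the new delay
        assert PlantParams(k_frac=kf, tau_delay=0.168).S == pytest.approx(S_ref)

    def test_constant_S_unchanged_delay(self):
        S_ref = PlantParams(k_frac=0.37, tau_delay=0.2).S
        assert stiffness_for_constant_S(0.2, S_ref) == pytest.approx(0.37, rel=1e-12)

    def test_zero_target_is_critical_stiffness(self):
        assert stiffness_for_constant_S(0.168, 0.0) == 1.0

    def test_unreachable_speed(self):
        with pytest.raises(ValueError, match="negative stiffness"):
            stiffness_for_constant_S(0.1, 1.0, tau_m0=0.32)
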