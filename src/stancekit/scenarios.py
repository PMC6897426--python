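"""Named adaptation strategies and parameter sweeps.

Two families of strategies are composed from the lower-level solvers:

* **Challenging balance conditions** (fixed delay): starting from a
  reference plant (50% critical stiffness, 0.14 s delay, critical PD
  gains), the sensorimotor gain is cut by a given percentage.  The *gain
  decrease* strategy applies the reduced gains at unchanged stiffness; the
  *co-adaptation* strategy additionally raises stiffness to the value at
  which the reduced proportional gain is exactly critical.  The derivative
  gain of both rows is the critical derivative gain of the co-adapted
  system (only this pairing keeps the gain-decrease row a pure "same
  controller, lower stiffness" variant of the co-adapted one).

* **Increased delay**: the delay grows by a given percentage.  *No
  adaptation* keeps the old gains; *gain adaptation* recomputes critical
  gains at the new delay and old stiffness; *co-adaptation* raises
  stiffness so the relative speed S is unchanged, then uses the critical
  gains (which, being functions of S alone in dimensionless form, shrink
  with the longer delay).

Every row is completed with the peak CoM and CoP excursions of the
simulated response to a unit perturbation; percent changes against the
reference are recomputed from the raw values (stiffness changes in
percentage points of the critical stiffness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criticality import (
    pd_critical,
    stiffness_for_constant_S,
    stiffness_for_critical_p,
)
from .dde import SimConfig, simulate
from .plant import DEFAULT_TAU_DELAY, DEFAULT_TAU_M0, PlantParams
from .stability import S_MAX, ControllerGains

__all__ = ["ScenarioRow", "ScenarioTable", "SweepGrid", "build_table1", "build_table2", "sweep"]

#: Reference plant of the strategy tables.
REFERENCE = PlantParams(tau_m0=DEFAULT_TAU_M0, k_frac=0.5, tau_delay=DEFAULT_TAU_DELAY)


@dataclass(frozen=True)
class ScenarioRow:
    name: str
    k_frac: float
    tau_delay: float
    p: float
    d: float
    peak_com: float
    peak_cop: float


@dataclass
class ScenarioTable:
    """Strategy rows plus percent changes recomputed against the reference."""

    title: str
    rows: list[ScenarioRow]
    reference: str = "Reference"

    def _ref(self) -> ScenarioRow:
        return next(r for r in self.rows if r.name == self.reference)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "stiffness_pct_kcrit": 100.0 * r.k_frac,
                    "delay_s": r.tau_delay,
                    "p": r.p,
                    "d": r.d,
                    "peak_com": r.peak_com,
                    "peak_cop": r.peak_cop,
                }
                for r in self.rows
            ]
        )

    def pct_changes(self) -> pd.DataFrame:
        """Changes vs the reference row; stiffness in points of K_crit, the
        rest in percent of the reference value."""
        ref = self._ref()
        out = []
        for r in self.rows:
            if r.name == self.reference:
                continue
            out.append(
                {
                    "name": r.name,
                    "stiffness_pts_kcrit": 100.0 * (r.k_frac - ref.k_frac),
                    "delay_pct": 100.0 * (r.tau_delay / ref.tau_delay - 1.0),
                    "p_pct": 100.0 * (r.p / ref.p - 1.0),
                    "d_pct": 100.0 * (r.d / ref.d - 1.0),
                    "peak_com_pct": 100.0 * (r.peak_com / ref.peak_com - 1.0),
                    "peak_cop_pct": 100.0 * (r.peak_cop / ref.peak_cop - 1.0),
                }
            )
        return pd.DataFrame(out)


def _simulated_row(
    name: str, k_frac: float, tau_delay: float, gains: ControllerGains,
    sim_config: SimConfig | None = None,
) -> ScenarioRow:
    params = REFERENCE.with_(k_frac=k_frac, tau_delay=tau_delay)
    res = simulate(params, gains, sim_config)
    return ScenarioRow(
        name=name,
        k_frac=k_frac,
        tau_delay=tau_delay,
        p=gains.p,
        d=gains.d,
        peak_com=res.peak_com,
        peak_cop=res.peak_cop,
    )


def _reference_row(sim_config: SimConfig | None = None) -> tuple[ScenarioRow, ControllerGains]:
    crit = pd_critical(REFERENCE.S, REFERENCE.tau_delay)
    row = _simulated_row(
        "Reference", REFERENCE.k_frac, REFERENCE.tau_delay, crit.gains, sim_config
    )
    return row, crit.gains


def build_table1(
    gain_decrease_pct: float = 15.0, sim_config: SimConfig | None = None
) -> ScenarioTable:
    """Strategies for standing in challenging balance conditions.

    Rows: Reference; Gain decrease (proportional gain cut by
    ``gain_decrease_pct`` at unchanged stiffness); Co-adaptation (stiffness
    raised so the reduced gain is exactly critical).  Both non-reference
    rows share the co-adapted critical gain pair.
    """
    ref_row, ref_gains = _reference_row(sim_config)
    tau = REFERENCE.tau_delay
    p_reduced = ref_gains.p * (1.0 - gain_decrease_pct / 100.0)
    k_co = stiffness_for_critical_p(p_reduced, tau, REFERENCE.tau_m0)
    co_plant = REFERENCE.with_(k_frac=k_co)
    co_gains = pd_critical(co_plant.S, tau).gains
    rows = [
        ref_row,
        _simulated_row("Gain decrease", REFERENCE.k_frac, tau, co_gains, sim_config),
        _simulated_row("Co-adaptation", k_co, tau, co_gains, sim_config),
    ]
    return ScenarioTable(title="Standing in challenging balance conditions", rows=rows)


def build_table2(
    delay_increase_pct: float = 20.0, sim_config: SimConfig | None = None
) -> ScenarioTable:
    """Strategies for compensating an increased neural delay.

    Rows: Reference; No adaptation (old gains at the new delay); Gain
    adaptation (critical gains recomputed at the new delay, old stiffness);
    Co-adaptation (stiffness raised to keep S constant, then critical
    gains).
    """
    ref_row, ref_gains = _reference_row(sim_config)
    tau_new = REFERENCE.tau_delay * (1.0 + delay_increase_pct / 100.0)
    ga_gains = pd_critical(
        REFERENCE.with_(tau_delay=tau_new).S, tau_new
    ).gains
    k_co = stiffness_for_constant_S(tau_new, REFERENCE.S, REFERENCE.tau_m0)
    co_gains = pd_critical(
        REFERENCE.with_(k_frac=k_co, tau_delay=tau_new).S, tau_new
    ).gains
    rows = [
        ref_row,
        _simulated_row("No adaptation", REFERENCE.k_frac, tau_new, ref_gains, sim_config),
        _simulated_row("Gain adaptation", REFERENCE.k_frac, tau_new, ga_gains, sim_config),
        _simulated_row("Co-adaptation", k_co, tau_new, co_gains, sim_config),
    ]
    return ScenarioTable(title="Compensating for increased delay", rows=rows)


@dataclass
class SweepGrid:
    """Surfaces of recovery time, critical gains and peak excursions over a
    (stiffness fraction) x (delay) grid.  Cells with S >= sqrt(2) are NaN."""

    k_frac: np.ndarray
    tau_delay: np.ndarray
    tau_balance: np.ndarray
    p_crit: np.ndarray
    d_crit: np.ndarray
    peak_com: np.ndarray
    peak_cop: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        kk, tt = np.meshgrid(self.k_frac, self.tau_delay, indexing="ij")
        return pd.DataFrame(
            {
                "k_frac": kk.ravel(),
                "tau_delay": tt.ravel(),
                "tau_balance": self.tau_balance.ravel(),
                "p_crit": self.p_crit.ravel(),
                "d_crit": self.d_crit.ravel(),
                "peak_com": self.peak_com.ravel(),
                "peak_cop": self.peak_cop.ravel(),
            }
        )


def sweep(
    k_frac_grid,
    tau_delay_grid,
    controller_kind: str = "PD",
    with_peaks: bool = True,
    sim_config: SimConfig | None = None,
    tau_m0: float = DEFAULT_TAU_M0,
) -> SweepGrid:
    """Critical-gain surfaces over a stiffness x delay grid.

    ``with_peaks=False`` skips the (comparatively expensive) simulations and
    leaves the peak surfaces NaN.
    """
    from .criticality import pd_damped_critical, pda_critical, pid_critical

    solvers = {
        "PD": lambda S, tau: pd_critical(S, tau),
        "PD_damped": lambda S, tau: pd_damped_critical(S, 0.0, tau),
        "PDA": lambda S, tau: pda_critical(S, tau),
        "PID": lambda S, tau: pid_critical(S, tau),
    }
    if controller_kind not in solvers:
        raise ValueError(f"unknown controller kind {controller_kind!r}")
    solver = solvers[controller_kind]

    kf = np.asarray(k_frac_grid, dtype=float)
    td = np.asarray(tau_delay_grid, dtype=float)
    shape = (len(kf), len(td))
    tb = np.full(shape, np.nan)
    pc = np.full(shape, np.nan)
    dc = np.full(shape, np.nan)
    com = np.full(shape, np.nan)
    cop = np.full(shape, np.nan)
    for ik, k in enumerate(kf):
        for it, tau in enumerate(td):
            plant = PlantParams(tau_m0=tau_m0, k_frac=k, tau_delay=tau)
            if plant.S >= S_MAX:
                continue  # no critically damped solution: cell left undefined
            sol = solver(plant.S, tau)
            tb[ik, it] = sol.tau_balance
            pc[ik, it] = sol.gains.p
            dc[ik, it] = sol.gains.d
            if with_peaks:
                res = simulate(plant, sol.gains, sim_config)
                com[ik, it] = res.peak_com
                cop[ik, it] = res.peak_cop
    return SweepGrid(
        k_frac=kf, tau_delay=td, tau_balance=tb, p_crit=pc, d_crit=dc,
        peak_com=com, peak_cop=cop,
    )
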