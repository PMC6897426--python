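"""Run configuration loading and validation (YAML)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dde import SimConfig
from .plant import (
    DEFAULT_TAU_DELAY,
    DEFAULT_TAU_M0,
    Perturbation,
    PlantParams,
    from_anthropometrics,
)
from .stability import ControllerGains

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Schema violation in a run configuration file."""


_PLANT_KEYS = {"tau_m0", "k_frac", "d_mech", "tau_delay"}
_DIMENSIONAL_KEYS = {"m", "g", "L", "J", "theta_eq_deg", "k"}
_CONTROLLER_KEYS = {"p", "d", "a", "i", "critical", "kind"}
_SIM_KEYS = {"dt", "horizon", "theta0", "thetadot0"}
_TOP_KEYS = {"plant", "controller", "simulation", "output", "verbosity", "seed"}


@dataclass
class RunConfig:
    """Validated run configuration with reference-system defaults."""

    plant: PlantParams = field(default_factory=PlantParams)
    gains: ControllerGains | None = None  # None -> critical PD gains
    controller_kind: str = "PD"
    sim: SimConfig = field(default_factory=SimConfig)
    output: str | None = None
    verbosity: int = 0
    seed: int = 0

    def resolve_gains(self) -> ControllerGains:
        """Explicit gains, or the critical PD gains of the plant."""
        if self.gains is not None:
            return self.gains
        from .criticality import pd_critical

        return pd_critical(self.plant.S, self.plant.tau_delay).gains


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def _parse_plant(block: dict) -> PlantParams:
    if _DIMENSIONAL_KEYS & set(block):
        _reject_unknown(block, _DIMENSIONAL_KEYS | {"tau_delay"}, "plant (dimensional)")
        import math

        try:
            return from_anthropometrics(
                m=float(block["m"]),
                g=float(block.get("g", 9.81)),
                L=float(block["L"]),
                J=float(block["J"]),
                theta_eq=math.radians(float(block.get("theta_eq_deg", 0.0))),
                k=float(block.get("k", 0.0)),
                tau_delay=float(block.get("tau_delay", DEFAULT_TAU_DELAY)),
            )
        except KeyError as exc:
            raise ConfigError(f"dimensional plant block missing key {exc}") from exc
    _reject_unknown(block, _PLANT_KEYS, "plant")
    try:
        return PlantParams(
            tau_m0=float(block.get("tau_m0", DEFAULT_TAU_M0)),
            k_frac=float(block.get("k_frac", 0.5)),
            d_mech=float(block.get("d_mech", 0.0)),
            tau_delay=float(block.get("tau_delay", DEFAULT_TAU_DELAY)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults: the reference plant (50% critical
    stiffness, 0.14 s delay) under critical PD control.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config root")

    plant = _parse_plant(raw.get("plant") or {})

    ctrl = raw.get("controller") or {}
    _reject_unknown(ctrl, _CONTROLLER_KEYS, "controller")
    gains = None
    if not ctrl.get("critical", not any(k in ctrl for k in ("p", "d", "a", "i"))):
        gains = ControllerGains(
            p=float(ctrl.get("p", 0.0)),
            d=float(ctrl.get("d", 0.0)),
            a=float(ctrl.get("a", 0.0)),
            i=float(ctrl.get("i", 0.0)),
        )
    kind = str(ctrl.get("kind", "PD"))
    if kind not in {"PD", "PD_damped", "PDA", "PID"}:
        raise ConfigError(f"unknown controller kind {kind!r}")

    sim_block = raw.get("simulation") or {}
    _reject_unknown(sim_block, _SIM_KEYS, "simulation")
    try:
        pert = Perturbation(
            theta0=float(sim_block.get("theta0", 1.0)),
            thetadot0=float(sim_block.get("thetadot0", 0.0)),
        )
        sim = SimConfig(
            dt=float(sim_block["dt"]) if "dt" in sim_block else None,
            horizon=float(sim_block.get("horizon", 6.0)),
            perturbation=pert,
            controller_kind=kind,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        plant=plant,
        gains=gains,
        controller_kind=kind,
        sim=sim,
        output=raw.get("output"),
        verbosity=int(raw.get("verbosity", 0)),
        seed=int(raw.get("seed", 0)),
    )
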