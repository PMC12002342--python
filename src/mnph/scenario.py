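"""Scenario generation: reference configuration, parameter ensembles, and
synthetic temperature histories.

Everything downstream of this module (bioheat solve, damage, sweeps) is
testable from here alone — no external data is ever required.  The reference
scenario is the treatment configuration used throughout: a 5 mm tumor nested
in a 15 mm skin cylinder, 30 mm tall, muscle-like tumor properties
(rho = 1090 kg/m^3, C_p = 3421 J/kg/K, k = 0.563 W/m/K, omega_b = 1.34e-2 1/s,
Q_met = 13.08 kW/m^3), skin properties (1109, 3391, 0.372, 1.96e-3, 1.83e3),
blood at (1050, 3617, 310.15 K), a uniform tumor source Q_nano = 214 kW/m^3,
convective skin surface with h = 3.6 W/m^2/K at 37 degC, initial temperature
37 degC, 60 minutes of heating.

Scenarios serialize to JSON (and read back from JSON or TOML) with a lossless
field-by-field round trip; ensembles use a single explicitly seeded generator
and are reproducible from (spec, seed) alone.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .bioheat import (
    BloodProperties,
    SimulationGrid,
    TissueMaterial,
    TissueModel,
)
from .constants import T_BODY

__all__ = [
    "EnsembleSpec",
    "SyntheticProfile",
    "default_scenario",
    "default_grid",
    "coarse_grid",
    "sample_ensemble",
    "synthetic_history",
    "scenario_to_dict",
    "scenario_from_dict",
    "write_scenario",
    "read_scenario",
    "PARAMETER_RANGES",
]

#: Uniform sampling bounds per parameter, matching the sensitivity-sweep grids.
PARAMETER_RANGES = {
    "omega_b": (0.001, 0.005),  # 1/s
    "rho_b": (700.0, 1100.0),  # kg/m^3
    "C_b": (2800.0, 4400.0),  # J/kg/K
    "Q_met": (1e3, 5e3),  # W/m^3
    "Q_nano": (110e3, 190e3),  # W/m^3
}


def default_scenario() -> TissueModel:
    """The reference treatment scenario (see module docstring)."""
    tumor = TissueMaterial(
        rho=1090.0, C_p=3421.0, k=0.563, omega_b=1.34e-2, Q_met=13.08e3
    )
    skin = TissueMaterial(
        rho=1109.0, C_p=3391.0, k=0.372, omega_b=1.96e-3, Q_met=1.83e3
    )
    return TissueModel(
        tumor_radius=5e-3,
        skin_radius=15e-3,
        height=30e-3,
        tumor=tumor,
        skin=skin,
        blood=BloodProperties(rho_b=1050.0, C_b=3617.0, T_b=T_BODY),
        Q_nano=214e3,
        h=3.6,
        T_ext=T_BODY,
        T_0=T_BODY,
    )


def default_grid() -> SimulationGrid:
    """Production resolution: dr = dz = 0.5 mm, dt = 1 s, 60 min."""
    return SimulationGrid(dr=0.5e-3, dz=0.5e-3, dt=1.0, duration=3600.0)


def coarse_grid(duration: float = 3600.0) -> SimulationGrid:
    """Screening resolution for sweeps: dr = dz = 1 mm, dt = 4 s."""
    return SimulationGrid(dr=1e-3, dz=1e-3, dt=4.0, duration=duration)


# -- parameter ensembles -----------------------------------------------------


@dataclass(frozen=True)
class EnsembleSpec:
    """Randomized single-parameter-space ensemble around a base scenario."""

    seed: int
    n: int
    ranges: dict = field(default_factory=lambda: dict(PARAMETER_RANGES))
    base: str = "default"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("ensemble size must be at least 1")
        for name, (lo, hi) in self.ranges.items():
            if name not in PARAMETER_RANGES:
                raise ValueError(f"unknown parameter {name!r}")
            if lo > hi:
                raise ValueError(f"empty range for {name!r}: ({lo}, {hi})")


def _apply_parameter(model: TissueModel, name: str, value: float) -> TissueModel:
    """Set one sweep parameter on a scenario; tissue-side parameters are
    applied to both tumor and skin domains, blood parameters are global."""
    if name == "omega_b":
        return replace(
            model,
            tumor=replace(model.tumor, omega_b=value),
            skin=replace(model.skin, omega_b=value),
        )
    if name == "Q_met":
        return replace(
            model,
            tumor=replace(model.tumor, Q_met=value),
            skin=replace(model.skin, Q_met=value),
        )
    if name == "rho_b":
        return replace(model, blood=replace(model.blood, rho_b=value))
    if name == "C_b":
        return replace(model, blood=replace(model.blood, C_b=value))
    if name == "Q_nano":
        return replace(model, Q_nano=value)
    raise ValueError(f"unknown parameter {name!r}")


def sample_ensemble(spec: EnsembleSpec) -> list[TissueModel]:
    """Draw n scenarios with every listed parameter sampled uniformly.

    A single seeded generator drives all draws; identical specs give
    identical ensembles.
    """
    rng = np.random.default_rng(spec.seed)
    base = default_scenario()
    out = []
    for _ in range(spec.n):
        model = base
        for name, (lo, hi) in spec.ranges.items():
            model = _apply_parameter(model, name, float(rng.uniform(lo, hi)))
        out.append(model)
    return out


# -- synthetic temperature histories ----------------------------------------


@dataclass(frozen=True)
class SyntheticProfile:
    """Parametric single-point temperature trace for damage-stage testing.

    kinds: ``constant`` (T = start), ``linear-ramp`` (start -> end over the
    full duration), ``ramp-plateau`` (start -> end over ramp_time, then hold),
    ``noisy-plateau`` (ramp-plateau plus seeded Gaussian noise).
    """

    kind: str = "constant"
    start: float = 310.15  # K
    end: float = 316.15  # K
    ramp_time: float = 300.0  # s
    noise: float = 0.0  # K (std of additive noise)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"constant", "linear-ramp", "ramp-plateau", "noisy-plateau"}:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        for T in (self.start, self.end):
            if not 273.15 <= T <= 373.15:
                raise ValueError("profile temperatures must stay within liquid water range")
        if self.noise < 0 or self.ramp_time < 0:
            raise ValueError("noise amplitude and ramp time cannot be negative")


def synthetic_history(profile: SyntheticProfile, dt: float, duration: float):
    """Deterministic (time, temperature) arrays of the requested shape.

    A constant profile makes the downstream damage integral exactly
    A_f * t * exp(-E_a/(R T)), enabling the closed-form oracle.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    times = np.arange(0.0, duration + dt / 2, dt)
    if profile.kind == "constant":
        temps = np.full_like(times, profile.start)
    elif profile.kind == "linear-ramp":
        temps = profile.start + (profile.end - profile.start) * times / duration
    else:  # ramp-plateau family
        if profile.ramp_time == 0:
            temps = np.full_like(times, profile.end)
        else:
            frac = np.clip(times / profile.ramp_time, 0.0, 1.0)
            temps = profile.start + (profile.end - profile.start) * frac
        if profile.kind == "noisy-plateau" and profile.noise > 0:
            rng = np.random.default_rng(profile.seed)
            temps = temps + rng.normal(0.0, profile.noise, size=times.shape)
    return times, temps


# -- serialization -----------------------------------------------------------


def scenario_to_dict(model: TissueModel, grid: SimulationGrid | None = None) -> dict:
    d = {"model": asdict(model)}
    d["model"]["convective_faces"] = list(model.convective_faces)
    if grid is not None:
        d["grid"] = asdict(grid)
    return d


def scenario_from_dict(d: dict) -> tuple[TissueModel, SimulationGrid | None]:
    md = dict(d["model"])
    md["tumor"] = TissueMaterial(**md["tumor"])
    md["skin"] = TissueMaterial(**md["skin"])
    md["blood"] = BloodProperties(**md["blood"])
    md["convective_faces"] = tuple(md.get("convective_faces", ("lateral",)))
    model = TissueModel(**md)
    grid = SimulationGrid(**d["grid"]) if "grid" in d else None
    return model, grid


def write_scenario(path, model: TissueModel, grid: SimulationGrid | None = None):
    """Write a scenario (and optionally its grid) as JSON."""
    Path(path).write_text(
        json.dumps(scenario_to_dict(model, grid), indent=2, sort_keys=True)
    )


def read_scenario(path) -> tuple[TissueModel, SimulationGrid | None]:
    """Read a scenario from JSON or TOML (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        d = tomllib.loads(path.read_text())
    else:
        d = json.loads(path.read_text())
    return scenario_from_dict(d)
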