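"""Run configuration: YAML/JSON loading, validation, and defaults.

A run configuration is a nested mapping with blocks ``material``,
``geometry``, ``load``, ``solver``, ``calibration`` plus top-level
``output_dir`` and ``seed``.  Unknown keys are rejected by name; omitted
material keys fall back to the Ti-6Al-4V reference values; all physical
values are validated at load time through the domain-type invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .integrate import StepControls
from .materials import MaterialParams
from .specimen import AreaProfile, hourglass_profile

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown keys, unparseable files, or invariant violations."""


_MATERIAL_KEYS = {
    "youngs_modulus_pa": "youngs_modulus",
    "poisson_ratio": "poisson_ratio",
    "beta_n": "beta_regularization",
    "eta_d_pa": "eta_d",
    "eta_p_pa": "eta_p",
    "r_d_pa": "r_d",
    "r_p_pa": "r_p",
    "k_hardening_pa": "k_hardening",
    "omega_hz": "omega",
    "plasticity_enabled": "plasticity_enabled",
}

_GEOMETRY_KEYS = {
    "gauge_diameter_m": 5e-3,
    "end_diameter_m": 12e-3,
    "gauge_length_m": 60e-3,
    "flat_length_m": 40e-3,
    "total_length_m": 60e-3,
    "waist_shape": "cosine",
    "n_elements": 64,
}

_LOAD_KEYS = {
    "amplitudes_mpa": [350.0, 400.0, 450.0, 500.0, 550.0, 600.0, 650.0],
    "control_mode": "displacement",
    "stress_ratio": -1.0,
    "max_cycles": 1e7,
}

_SOLVER_KEYS = {
    "delta_d_max": 0.01,
    "delta_n_min": 1e-3,
    "delta_n_max": None,
    "failure_fraction": 0.1,
    "sub_step_bisection_tol": 1e-9,
    "scheme": "explicit",
}

_CALIBRATION_KEYS = {
    "anchors": [[350.0, 1_261_680.0], [600.0, 34_536.0]],
    "free": ["r_d", "eta_d_omega"],
    "engine": "specimen",
}

_TOP_KEYS = {"material", "geometry", "load", "solver", "calibration", "output_dir", "seed"}


def _check_block(name: str, block: dict, allowed) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {name!r} block: {sorted(unknown)}")


def _coerce_number(name: str, value):
    """Allow YAML-1.1 scientific-notation strings like '3.5e5' for numbers."""
    if isinstance(value, bool) or value is None:
        return value
    if isinstance(value, (int, float)):
        return value
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"key {name!r} must be numeric, got {value!r}") from exc


@dataclass
class RunConfig:
    """Fully validated configuration for simulation, sweep, and calibration runs."""

    material: MaterialParams
    geometry: dict[str, Any]
    load: dict[str, Any]
    solver: StepControls
    calibration: dict[str, Any]
    output_dir: str = "."
    seed: int = 0

    def profile(self) -> AreaProfile:
        g = self.geometry
        return hourglass_profile(
            gauge_diameter=g["gauge_diameter_m"],
            end_diameter=g["end_diameter_m"],
            gauge_length=g["gauge_length_m"],
            total_length=g["total_length_m"],
            waist_shape=g["waist_shape"],
            flat_length=g["flat_length_m"],
        )

    @property
    def n_elements(self) -> int:
        return int(self.geometry["n_elements"])

    def to_dict(self) -> dict[str, Any]:
        m = self.material
        return {
            "material": {
                "youngs_modulus_pa": m.youngs_modulus,
                "poisson_ratio": m.poisson_ratio,
                "beta_n": m.beta_regularization,
                "eta_d_pa": m.eta_d,
                "eta_p_pa": m.eta_p,
                "r_d_pa": m.r_d,
                "r_p_pa": m.r_p,
                "k_hardening_pa": m.k_hardening,
                "omega_hz": m.omega,
                "plasticity_enabled": m.plasticity_enabled,
            },
            "geometry": dict(self.geometry),
            "load": dict(self.load),
            "solver": {
                "delta_d_max": self.solver.delta_d_max,
                "delta_n_min": self.solver.delta_n_min,
                "delta_n_max": self.solver.delta_n_max,
                "failure_fraction": self.solver.failure_fraction,
                "sub_step_bisection_tol": self.solver.sub_step_bisection_tol,
                "scheme": self.solver.scheme,
            },
            "calibration": dict(self.calibration),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

        mat_block = raw.get("material") or {}
        _check_block("material", mat_block, _MATERIAL_KEYS)
        try:
            material = MaterialParams(
                **{
                    _MATERIAL_KEYS[k]: (v if k == "plasticity_enabled" else _coerce_number(k, v))
                    for k, v in mat_block.items()
                }
            )
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid material block: {exc}") from exc

        geometry = dict(_GEOMETRY_KEYS)
        geo_block = raw.get("geometry") or {}
        _check_block("geometry", geo_block, _GEOMETRY_KEYS)
        geometry.update(geo_block)

        load = dict(_LOAD_KEYS)
        load_block = raw.get("load") or {}
        _check_block("load", load_block, _LOAD_KEYS)
        load.update(load_block)
        if load["control_mode"] not in ("displacement", "stress", "strain"):
            raise ConfigError(f"invalid load.control_mode {load['control_mode']!r}")

        solver_kwargs = dict(_SOLVER_KEYS)
        solver_block = raw.get("solver") or {}
        _check_block("solver", solver_block, _SOLVER_KEYS)
        solver_kwargs.update(solver_block)
        try:
            solver = StepControls(**solver_kwargs)
        except ValueError as exc:
            raise ConfigError(f"invalid solver block: {exc}") from exc

        calibration = dict(_CALIBRATION_KEYS)
        cal_block = raw.get("calibration") or {}
        _check_block("calibration", cal_block, _CALIBRATION_KEYS)
        calibration.update(cal_block)

        cfg = cls(
            material=material,
            geometry=geometry,
            load=load,
            solver=solver,
            calibration=calibration,
            output_dir=str(raw.get("output_dir", ".")),
            seed=int(raw.get("seed", 0)),
        )
        # geometry invariants surface early, naming the offending values
        try:
            cfg.profile()
        except ValueError as exc:
            raise ConfigError(f"invalid geometry block: {exc}") from exc
        return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON — a YAML subset) run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable config {path}: {exc}") from exc
    return RunConfig.from_dict(raw or {})
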