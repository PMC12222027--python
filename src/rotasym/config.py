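"""Run configuration: packaged motor constants and the YAML schema.

The default configuration collects the numeric constants the analyses rest
on — stator counts, the per-stator force, stator–rotor contact radii, and
the basal-disk lattice parameters — together with generator defaults and a
seed.  Constants carry a provenance tag: ``literature`` for values taken
from published measurements, ``derived`` for structural constants this
package derives from those (e.g. contact radii consistent with the torque
predictions), so users can see at a glance which numbers to override with
their own measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "default_config_dict", "load_config", "CONFIG_SCHEMA_VERSION"]

CONFIG_SCHEMA_VERSION = 1


def default_config_dict() -> dict[str, Any]:
    """The packaged default configuration for the *C. jejuni* motor."""
    return {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "seed": 1,
        "constants": {
            "cjejuni": {
                "n_stators": 17,            # literature: stator ring count
                "force_pN": 7.3,            # literature: per-stator force
                "radius_nm": 26.5,          # derived: contact radius
                "cring_teeth": 38,          # literature: C-ring periodicity
                "scaffold_symmetry": 17,    # literature: periplasmic scaffold
                "inner_ring_protomers": 51, # literature: 17 trimers
                "spacing_ratio": 0.216,     # derived: Δr/R1 giving +11/ring
            },
            "ecoli": {
                "n_stators": 11,            # literature
                "force_pN": 7.3,            # literature
                "radius_nm": 20.0,          # derived: contact radius
                "cring_teeth": 34,          # literature
            },
        },
        "disk": {"n_rings": 5, "R1_A": 180.0},
        "bead_sim": {
            "n_steps_per_rev": 26,
            "step_rate": 50.0,
            "frames": 100_000,
            "fps": 1000.0,
            "orbit": {"centre": [0.0, 0.0], "a": 150.0, "b": 90.0, "tilt": 0.4},
            "noise_sd": 20.0,
            "back_step_prob": 0.0,
        },
        "stages": ["torque_predictions", "disk_rings"],
        "output_dir": None,
    }


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    constants: dict[str, Any]
    disk: dict[str, Any]
    bead_sim: dict[str, Any]
    stages: list[str]
    output_dir: str | None = None
    schema_version: int = CONFIG_SCHEMA_VERSION

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        merged = default_config_dict()
        for key, value in raw.items():
            if key not in merged:
                raise ValueError(f"unknown config field: {key!r}")
            if isinstance(merged[key], dict) and isinstance(value, dict):
                merged[key].update(value)
            else:
                merged[key] = value
        if merged["schema_version"] != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"config schema_version {merged['schema_version']} != {CONFIG_SCHEMA_VERSION}"
            )
        _validate_positive(merged["constants"], "constants")
        if not isinstance(merged["stages"], list):
            raise ValueError("stages: must be a list of stage names")
        return cls(
            seed=int(merged["seed"]),
            constants=merged["constants"],
            disk=merged["disk"],
            bead_sim=merged["bead_sim"],
            stages=list(merged["stages"]),
            output_dir=merged["output_dir"],
        )

    @classmethod
    def defaults(cls, **overrides: Any) -> "RunConfig":
        return cls.from_dict(overrides)


def _validate_positive(node: Any, path: str) -> None:
    """All numeric constants must be positive; report the offending field path."""
    if isinstance(node, dict):
        for key, value in node.items():
            _validate_positive(value, f"{path}.{key}")
    elif isinstance(node, (int, float)):
        if not node > 0:
            raise ValueError(f"config constant {path} must be > 0, got {node}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return RunConfig.from_dict(raw)
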