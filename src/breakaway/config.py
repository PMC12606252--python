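"""Scenario configuration: strict YAML/JSON loading and saving.

A scenario file has a ``dimensionless:`` block (the model's native
parameters) and/or a ``physical:`` block (dimensional rider/course values
from which the scales are derived). Dimensionless values win when both are
present. Unknown keys are rejected outright — silently ignoring a misspelled
parameter would corrupt a study.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import yaml

from .scenario import (
    ConfigurationError,
    DragProfile,
    OffsetConvention,
    PhysicalParameters,
    RaceScenario,
    nondimensionalize,
)

_PHYSICAL_KEYS = {
    "rider_mass_kg": "rider_mass",
    "mean_mass_kg": "mean_mass",
    "rho": "air_density",
    "area_m2": "frontal_area",
    "length_m": "course_length",
    "axle_spacing_m": "axle_spacing",
    "mean_power_w": "mean_initial_power",
}
_DIMENSIONLESS_KEYS = {
    "cd1": "cd1",
    "cd_lurk": "cd_lurk",
    "position": "lurk_position",
    "n_riders": "n_riders",
    "omega": "omega",
    "crash_rate": "crash_rate",
    "energy_budget": "energy_budget",
    "beta": "beta",
}
_DRAG_KEYS = {
    "cd_max": "cd_max",
    "cd_min": "cd_min",
    "decay": "decay",
    "peloton_mean_cd": "peloton_mean_cd",
    "offset_convention": "offset_convention",
}
_TOP_KEYS = {"physical", "dimensionless", "drag"}


class ValidationError(ConfigurationError):
    """A config file violates the schema (unknown keys or bad values)."""


def _check_keys(block: dict[str, Any], allowed: dict[str, str], name: str) -> None:
    unknown = sorted(set(block) - set(allowed))
    if unknown:
        raise ValidationError(f"unknown keys in '{name}' block: {', '.join(unknown)}")


def _parse(text: str, suffix: str) -> dict[str, Any]:
    if suffix in {".json"}:
        return json.loads(text)
    return yaml.safe_load(text)


def load_scenario(
    path: str | Path,
) -> tuple[RaceScenario, PhysicalParameters | None]:
    """Load and validate a scenario file (YAML or JSON).

    Returns the dimensionless scenario plus the physical parameters when a
    ``physical:`` block was given. With only a physical block, the
    dimensionless drags are derived from the drag profile and the scenario
    falls back to defaults for the probabilistic parameters.
    """
    path = Path(path)
    raw = _parse(path.read_text(), path.suffix.lower())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise ValidationError(f"unknown top-level keys: {', '.join(unknown)}")
    if not raw:
        raise ValidationError(f"{path}: empty configuration")

    drag_block = raw.get("drag", {}) or {}
    _check_keys(drag_block, _DRAG_KEYS, "drag")
    drag_kwargs = {dest: drag_block[src] for src, dest in _DRAG_KEYS.items() if src in drag_block}
    if "offset_convention" in drag_kwargs:
        drag_kwargs["offset_convention"] = OffsetConvention(drag_kwargs["offset_convention"])
    profile = DragProfile(**drag_kwargs) if drag_kwargs else DragProfile()

    overrides: dict[str, Any] = {}
    if "dimensionless" in raw:
        block = raw["dimensionless"] or {}
        _check_keys(block, _DIMENSIONLESS_KEYS, "dimensionless")
        overrides = {dest: block[src] for src, dest in _DIMENSIONLESS_KEYS.items() if src in block}

    phys: PhysicalParameters | None = None
    derived: dict[str, Any] = {}
    if "physical" in raw:
        block = raw["physical"] or {}
        _check_keys(block, _PHYSICAL_KEYS, "physical")
        try:
            phys = PhysicalParameters(
                **{dest: float(block[src]) for src, dest in _PHYSICAL_KEYS.items() if src in block}
            )
        except (TypeError, ConfigurationError) as exc:
            raise ValidationError(f"invalid physical block: {exc}") from exc
        if profile.peloton_mean_cd is not None:
            position = int(overrides.get("lurk_position", RaceScenario().lurk_position))
            # A solo rider (and the front of the peloton) carries the full drag.
            derived["cd1"] = profile.cd_max / profile.peloton_mean_cd
            derived["cd_lurk"] = profile.rescaled_drag(position)

    scenario_kwargs = dict(derived)
    scenario_kwargs.update(overrides)
    try:
        scenario = RaceScenario(**scenario_kwargs)
    except ConfigurationError as exc:
        raise ValidationError(str(exc)) from exc
    return scenario, phys


def save_scenario(scenario: RaceScenario, path: str | Path) -> None:
    """Write a scenario as a dimensionless YAML/JSON block (load round-trips)."""
    path = Path(path)
    inverse = {dest: src for src, dest in _DIMENSIONLESS_KEYS.items()}
    block = {inverse[k]: v for k, v in asdict(scenario).items()}
    payload = {"dimensionless": block}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def resolved_sidecar(scenario: RaceScenario, phys: PhysicalParameters | None = None) -> str:
    """JSON text of the fully resolved scenario (written next to CSV outputs)."""
    payload: dict[str, Any] = {"dimensionless": asdict(scenario)}
    if phys is not None:
        payload["physical"] = asdict(phys)
        scales = nondimensionalize(phys, DragProfile())
        payload["scales"] = asdict(scales)
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
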