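"""Scenario configuration: presets, JSON loading/validation, output writing.

A scenario bundles model parameters, a detachment schedule, an initial
state and integration controls.  Severities may be given either as raw
factors (``delta0``, ``gamma0``) or as percent changes relative to normal
(``delta_reduction_percent``, ``gamma_reduction_percent``; negative values
mean an increase).  When both are supplied the raw factor wins and a
warning is logged.

The named presets reproduce the canonical detachment regimes at the
default (mouse) parameters:

========  =======  =======  =====================================================
preset    δ0       γ0       scenario
========  =======  =======  =====================================================
fig3      1        1        normal renewal from a single nascent disc
fig4      0.0136   0        addition reduced 98.64%, removal halted
fig5      0        0        both processes halted (frozen; length conserved)
fig6      0        0.625    addition halted, removal reduced 37.5%
fig7a     0.0068   1.875    addition reduced 99.32%, removal increased 87.5%
fig7b     0.0164   0.625    addition reduced 98.36%, removal reduced 37.5%
========  =======  =======  =====================================================
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CompartmentState, DetachmentSchedule, ModelParameters
from .simulate import DEFAULT_GRID_STEP, DEFAULT_HORIZON

__all__ = ["Scenario", "ConfigError", "PRESETS", "preset", "load_config", "scenario_from_dict", "write_outputs"]

logger = logging.getLogger("rosdyn")

_PARAM_KEYS = ("mu0", "alpha_g", "alpha_s", "mu_s", "Lmax", "delta_T", "delta_s")


class ConfigError(ValueError):
    """Invalid scenario configuration; the message lists every offending key."""


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation scenario."""

    name: str
    params: ModelParameters
    schedule: DetachmentSchedule
    initial: CompartmentState
    horizon: float = DEFAULT_HORIZON
    grid_step: float = DEFAULT_GRID_STEP
    description: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parameters": {k: getattr(self.params, k) for k in _PARAM_KEYS},
            "schedule": {
                "delta0": self.schedule.delta0,
                "gamma0": self.schedule.gamma0,
                "Ta": "inf" if self.schedule.Ta == float("inf") else self.schedule.Ta,
            },
            "initial": {"lengths_um": [self.initial.Lg, self.initial.Lm, self.initial.Ls]},
            "horizon_days": self.horizon,
            "grid_step_days": self.grid_step,
        }


def _preset(name, delta0, gamma0, initial_discs, description, horizon=DEFAULT_HORIZON):
    params = ModelParameters()
    return Scenario(
        name=name,
        params=params,
        schedule=DetachmentSchedule(delta0=delta0, gamma0=gamma0),
        initial=CompartmentState.from_discs(*initial_discs, params.geometry),
        horizon=horizon,
        description=description,
    )


#: Canonical detachment scenarios at default parameters.  All presets except
#: the normal-renewal one start from the adult state (94, 627, 157) discs
#: ≈ (3, 20, 5) μm; the detachment persists (Ta = ∞).
PRESETS: dict[str, Scenario] = {
    "fig3": _preset("fig3", 1.0, 1.0, (1, 0, 0),
                    "normal renewal of a developing ROS from a single nascent disc",
                    horizon=60.0),
    "fig4": _preset("fig4", 0.0136, 0.0, (94, 627, 157),
                    "addition reduced by 98.64%, removal halted: unbounded growth"),
    "fig5": _preset("fig5", 0.0, 0.0, (94, 627, 157),
                    "addition and removal both halted: total length conserved"),
    "fig6": _preset("fig6", 0.0, 0.625, (94, 627, 157),
                    "addition halted, removal reduced by 37.5%: decay to zero"),
    "fig7a": _preset("fig7a", 0.0068, 1.875, (94, 627, 157),
                     "addition reduced by 99.32%, removal increased by 87.5%"),
    "fig7b": _preset("fig7b", 0.0164, 0.625, (94, 627, 157),
                     "addition reduced by 98.36%, removal reduced by 37.5%"),
}


def preset(name: str) -> Scenario:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def _severity(block: dict, raw_key: str, pct_key: str, default: float, errors: list[str]) -> float:
    raw = block.get(raw_key)
    pct = block.get(pct_key)
    if raw is not None and pct is not None:
        logger.warning("both %s and %s given; raw factor %s wins", raw_key, pct_key, raw_key)
        return float(raw)
    if raw is not None:
        return float(raw)
    if pct is not None:
        return 1.0 - float(pct) / 100.0
    return default


def scenario_from_dict(cfg: dict, name: str = "config") -> Scenario:
    """Validate a configuration mapping and build a scenario.

    Unknown keys and invariant violations are collected and reported
    together in a single :class:`ConfigError`.
    """
    errors: list[str] = []
    base = preset(cfg["preset"]) if "preset" in cfg else None

    known_top = {"preset", "name", "parameters", "schedule", "initial", "horizon_days", "grid_step_days"}
    errors += [f"unknown top-level key {k!r}" for k in cfg if k not in known_top]

    pblock = dict(cfg.get("parameters", {}))
    errors += [f"unknown parameter key {k!r}" for k in pblock if k not in _PARAM_KEYS]
    pdefaults = {k: getattr(base.params if base else ModelParameters(), k) for k in _PARAM_KEYS}
    pdefaults.update({k: v for k, v in pblock.items() if k in _PARAM_KEYS})
    params = None
    try:
        params = ModelParameters(**pdefaults)
    except (TypeError, ValueError) as err:
        errors.append(f"parameters: {err}")

    sblock = dict(cfg.get("schedule", {}))
    known_sched = {"delta0", "gamma0", "Ta", "delta_reduction_percent", "gamma_reduction_percent"}
    errors += [f"unknown schedule key {k!r}" for k in sblock if k not in known_sched]
    sched_default = base.schedule if base else DetachmentSchedule.normal()
    delta0 = _severity(sblock, "delta0", "delta_reduction_percent", sched_default.delta0, errors)
    gamma0 = _severity(sblock, "gamma0", "gamma_reduction_percent", sched_default.gamma0, errors)
    ta = sblock.get("Ta", sched_default.Ta)
    ta = float("inf") if ta in (None, "inf") else float(ta)
    schedule = None
    try:
        schedule = DetachmentSchedule(delta0=delta0, gamma0=gamma0, Ta=ta)
    except ValueError as err:
        errors.append(f"schedule: {err}")

    iblock = dict(cfg.get("initial", {}))
    errors += [
        f"unknown initial key {k!r}" for k in iblock if k not in {"discs", "lengths_um"}
    ]
    initial = base.initial if base else None
    if "discs" in iblock and "lengths_um" in iblock:
        errors.append("initial: give either 'discs' or 'lengths_um', not both")
    elif "discs" in iblock or "lengths_um" in iblock:
        key = "discs" if "discs" in iblock else "lengths_um"
        vals = iblock[key]
        if not (isinstance(vals, (list, tuple)) and len(vals) == 3):
            errors.append(f"initial.{key}: expected a 3-element list (G, M, S)")
        elif params is not None:
            try:
                initial = (
                    CompartmentState.from_discs(*vals, params.geometry)
                    if key == "discs"
                    else CompartmentState(*map(float, vals))
                )
            except ValueError as err:
                errors.append(f"initial: {err}")
    elif initial is None:
        errors.append("initial: missing (give 'discs' or 'lengths_um', or start from a preset)")

    horizon = float(cfg.get("horizon_days", base.horizon if base else DEFAULT_HORIZON))
    grid_step = float(cfg.get("grid_step_days", base.grid_step if base else DEFAULT_GRID_STEP))
    if horizon <= 0:
        errors.append("horizon_days must be positive")
    if not 0 < grid_step <= horizon:
        errors.append("grid_step_days must lie in (0, horizon_days]")

    if errors:
        raise ConfigError("invalid scenario configuration:\n  - " + "\n  - ".join(errors))
    return Scenario(
        name=str(cfg.get("name", cfg.get("preset", name))),
        params=params,
        schedule=schedule,
        initial=initial,
        horizon=horizon,
        grid_step=grid_step,
    )


def load_config(path) -> Scenario:
    """Load and validate a JSON scenario configuration file."""
    path = Path(path)
    try:
        cfg = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ConfigError(f"{path}: not valid JSON ({err})") from err
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a JSON object")
    return scenario_from_dict(cfg, name=path.stem)


def write_outputs(tables: dict, scenario: Scenario | None, out_dir, seed: int | None = None) -> list[Path]:
    """Write result tables plus a deterministic run manifest.

    ``tables`` maps file names to DataFrames (written as CSV) or JSON-able
    mappings (written as JSON).  The manifest records the scenario, its
    SHA-256 hash, the seed and the package version, so reruns of
    deterministic subcommands are byte-identical.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fname, obj in tables.items():
        target = out / fname
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(target, index=False, float_format="%.10g")
        else:
            target.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
        written.append(target)
    manifest = {
        "package": "rosdyn",
        "version": __version__,
        "seed": seed,
        "scenario": scenario.to_dict() if scenario else None,
    }
    blob = json.dumps(manifest, sort_keys=True, default=_json_default)
    manifest["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    target = out / "manifest.json"
    target.write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")
    written.append(target)
    return written


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if obj == float("inf"):
        return "inf"
    return str(obj)
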