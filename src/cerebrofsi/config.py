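"""YAML configuration: one file drives geometry, rheology, wall and solvers.

Blocks: ``scenario:``, ``rheology:``, ``wall:``, ``bcs:``, ``solver:``,
``coupling:`` -- each optional, each overriding the study defaults.  Numeric
entries may carry units as strings (``"16 kPa"``, ``"120 mmHg"``,
``"0.04 g/(cm.s)"``); everything is converted to SI on load.  The historical
CGS blood viscosity 0.04 g/(cm s) becomes 0.004 Pa s, and 120 mmHg converts
with the exact definition 1 mmHg = 133.322387415 Pa (so the study's 16 kPa
inlet datum and "~120 mmHg" agree to 0.01%).
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field, fields, replace
from typing import Optional

import yaml

from .flow_solver import FlowBCs, SolverSettings
from .fsi_coupling import CouplingSettings
from .rheology import RheologyParams
from .scenario_geometry import (Branch, Scenario, ScenarioSpec, StenosisSpec,
                                WallSide, default_spec)
from .wall_mechanics import WallMaterial

__all__ = [
    "MMHG_TO_PA", "parse_quantity", "PipelineConfig", "load_config",
    "default_config", "config_to_yaml",
]

MMHG_TO_PA = 133.322387415          # exact conventional definition

_UNIT_FACTORS = {
    # pressure
    "pa": 1.0, "kpa": 1e3, "mpa": 1e6, "mmhg": MMHG_TO_PA,
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "micron": 1e-6,
    # viscosity
    "pa.s": 1.0, "pa*s": 1.0, "g/(cm.s)": 0.1, "g/(cm*s)": 0.1, "poise": 0.1,
    # velocity
    "m/s": 1.0, "cm/s": 1e-2, "mm/s": 1e-3,
    # density
    "kg/m3": 1.0, "kg/m^3": 1.0, "g/cm3": 1e3, "g/cm^3": 1e3,
    # time / rate / angle / dimensionless
    "s": 1.0, "1/s": 1.0, "deg": 1.0, "": 1.0,
}


def parse_quantity(value) -> float:
    """Convert ``3.2``, ``"3.2 mm"``, ``"120 mmHg"`` ... to an SI float."""
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise TypeError(f"cannot parse quantity {value!r}")
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([^\s]*)\s*", value)
    if not m:
        raise ValueError(f"malformed quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2).lower()
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {m.group(2)!r} in {value!r}")
    return num * _UNIT_FACTORS[unit]


def _build(cls, block: dict, converters: dict | None = None):
    """Instantiate a dataclass from a config block with unit conversion."""
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, raw in (block or {}).items():
        if key not in known:
            raise KeyError(f"unknown key {key!r} for {cls.__name__}")
        if converters and key in converters:
            kwargs[key] = converters[key](raw)
        elif isinstance(raw, (int, float, str)) and not isinstance(raw, bool):
            try:
                kwargs[key] = parse_quantity(raw)
            except (TypeError, ValueError):
                kwargs[key] = raw
        else:
            kwargs[key] = raw
    return cls(**kwargs)


def _parse_stenosis(entry: dict) -> StenosisSpec:
    entry = dict(entry)
    side = entry.pop("side", None)
    return StenosisSpec(
        branch=Branch(entry.pop("branch", "parent")),
        center_offset=parse_quantity(entry.pop("center_offset", 4.8e-3)),
        length=parse_quantity(entry.pop("length", 1.6e-3)),
        degree=float(entry.pop("degree", 0.5)),
        side=WallSide(side) if side else None,
    )


@dataclass
class PipelineConfig:
    """Fully resolved run configuration (SI units everywhere)."""

    scenarios: tuple = (Scenario.INTACT, Scenario.ICAS, Scenario.ACA)
    scenario_overrides: dict = field(default_factory=dict)
    rheology: RheologyParams = field(default_factory=RheologyParams)
    wall: WallMaterial = field(default_factory=WallMaterial)
    bcs: FlowBCs = field(default_factory=FlowBCs)
    solver: SolverSettings = field(default_factory=SolverSettings)
    coupling: CouplingSettings = field(default_factory=CouplingSettings)
    series_steps: Optional[int] = None   # ramp steps recorded in the report

    def spec_for(self, scenario: Scenario | str) -> ScenarioSpec:
        spec = default_spec(scenario, **{
            k: v for k, v in self.scenario_overrides.items()
            if k != "stenoses"})
        if "stenoses" in self.scenario_overrides \
                and Scenario(scenario) != Scenario.INTACT:
            spec = replace(spec, stenoses=tuple(
                self.scenario_overrides["stenoses"]))
        return spec


def load_config(source) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML path, text, or dict."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, dict):
        raw = source
    else:
        text = source
        if "\n" not in str(source):
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, TypeError):
                pass
        raw = yaml.safe_load(text) or {}

    scen_block = dict(raw.get("scenario", {}))
    scenarios = scen_block.pop("scenarios", None) or raw.get(
        "scenarios", ["intact", "icas", "aca"])
    if isinstance(scenarios, str):
        scenarios = [scenarios]
    overrides = {}
    for key, val in scen_block.items():
        if key == "stenoses":
            overrides["stenoses"] = tuple(_parse_stenosis(s) for s in val)
        elif key in ("seed",):
            overrides[key] = int(val)
        elif key == "scenario":
            continue
        else:
            overrides[key] = parse_quantity(val)

    rheo_block = dict(raw.get("rheology", {}))
    if "viscosity" in rheo_block:       # the historical CGS name
        rheo_block["mu_ref"] = rheo_block.pop("viscosity")

    cfg = PipelineConfig(
        scenarios=tuple(Scenario(s) for s in scenarios),
        scenario_overrides=overrides,
        rheology=_build(RheologyParams, rheo_block),
        wall=_build(WallMaterial, raw.get("wall", {})),
        bcs=_build(FlowBCs, raw.get("bcs", {}),
                   converters={"inlet_profile": str}),
        solver=_build(SolverSettings, raw.get("solver", {}),
                      converters={"picard_max_iters": int,
                                  "ramp_steps": int}),
        coupling=_build(CouplingSettings, raw.get("coupling", {}),
                        converters={"max_outer_iters": int,
                                    "relaxation": str,
                                    "prestress": bool,
                                    "relaxation_clamp": tuple}),
    )
    if "series_steps" in raw:
        cfg.series_steps = int(raw["series_steps"])
    return cfg


def default_config() -> PipelineConfig:
    return PipelineConfig()


def config_to_yaml(cfg: PipelineConfig) -> str:
    """Echo a resolved configuration as YAML (SI units)."""
    out = {
        "scenarios": [s.value for s in cfg.scenarios],
        "scenario": {k: (v if not isinstance(v, tuple) else
                         [asdict(s) if hasattr(s, "__dataclass_fields__")
                          else s for s in v])
                     for k, v in cfg.scenario_overrides.items()},
        "rheology": asdict(cfg.rheology),
        "wall": asdict(cfg.wall),
        "bcs": asdict(cfg.bcs),
        "solver": asdict(cfg.solver),
        "coupling": asdict(cfg.coupling),
    }
    if cfg.series_steps is not None:
        out["series_steps"] = cfg.series_steps

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if hasattr(obj, "value"):
            return obj.value
        return obj

    return yaml.safe_dump(clean(out), sort_keys=False)
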