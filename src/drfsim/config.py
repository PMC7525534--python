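"""Structured-text (YAML) configuration files.

A config file bundles a scenario (builder name + overrides), parameter
sets and simulation settings under a versioned schema:

    schema: drfsim-config v1
    scenario:
      name: oncoming
      overrides: {variant: absent}
    preset: normal          # or an explicit driver: {...} block
    drf: {t_la: 3.5}        # optional field-parameter overrides
    sim: {dt: 0.05}         # optional SimConfig overrides

Angle values may be given as strings with an explicit ``deg`` suffix.
"""

from __future__ import annotations

import math
from dataclasses import replace

import yaml

from .controller import DriverParams
from .field import DRFParams
from .presets import DRF_DEFAULT, get_preset
from .scene import Scenario, build_scenario
from .simulator import SimConfig

SCHEMA = "drfsim-config v1"

__all__ = ["SCHEMA", "load_config", "save_config"]


def _convert(value):
    if isinstance(value, str) and value.endswith("deg"):
        return math.radians(float(value[:-3]))
    if isinstance(value, dict):
        return {k: _convert(v) for k, v in value.items()}
    return value


def load_config(path):
    """Read a config file -> (Scenario, DRFParams, DriverParams, SimConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if raw.get("schema") != SCHEMA:
        raise ValueError(
            f"unsupported config schema {raw.get('schema')!r}; expected {SCHEMA!r}")
    sc_block = raw.get("scenario", {})
    scenario = build_scenario(sc_block.get("name", "lane_width"),
                              _convert(sc_block.get("overrides", {})))
    drf = replace(DRF_DEFAULT, **_convert(raw.get("drf", {})))
    if "driver" in raw:
        driver = DriverParams(**_convert(raw["driver"]))
    else:
        driver = get_preset(raw.get("preset", "normal"))
    cfg = SimConfig(**_convert(raw.get("sim", {})))
    return scenario, drf, driver, cfg


def save_config(path, scenario_name: str, overrides: dict | None = None,
                preset: str = "normal", drf: dict | None = None,
                sim: dict | None = None) -> None:
    doc = {"schema": SCHEMA,
           "scenario": {"name": scenario_name,
                        "overrides": overrides or {}},
           "preset": preset}
    if drf:
        doc["drf"] = drf
    if sim:
        doc["sim"] = sim
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
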