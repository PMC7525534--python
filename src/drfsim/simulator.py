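"""Closed-loop simulation: scene -> field -> risk -> decision -> kinematics.

Each step rasterizes the scene cost map on a moving window aligned with
the vehicle, evaluates the risk field at the current state, computes the
perceived risk, takes one satisficing control decision, and advances the
kinematic bicycle.  Everything is logged per step; the run terminates at
the configured duration or at the end of the road.  Obstacles are placed
at their current-time station — the model makes no prediction of their
motion, a stated limitation it inherits deliberately.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field as dfield

import numpy as np
import pandas as pd

from .controller import REF_CELL, DriverParams, RiskEvaluator, decide
from .field import DRFParams, FieldGrid
from .kinematics import VehicleSpec, VehicleState, step, wrap_angle
from .scene import Scenario, rasterize

__all__ = ["SimConfig", "TrajectoryLog", "run", "write_log", "read_log"]

LOG_VERSION = "drfsim-log v1"
LOG_COLUMNS = ["t", "x", "y", "phi", "v", "delta", "c_k", "case", "station", "e"]


@dataclass(frozen=True)
class SimConfig:
    """Numerical configuration of the closed loop."""

    dt: float = 0.05
    grid_delta: float = 0.25
    lat_extent: float = 15.0
    back_extent: float = 2.0
    fwd_factor: float = 1.2
    fwd_margin: float = 10.0
    end_margin: float = 5.0
    duration: float | None = None  # None -> scenario default
    literal_step_updates: bool = False
    delta_max: float | None = math.pi / 4
    avoidance_blend: float = 0.05
    horizon_env_penalty: bool = True
    seed: int | None = None  # fixture noise only; the loop is deterministic

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.grid_delta > 0):
            raise ValueError("dt and grid_delta must be > 0")


@dataclass
class TrajectoryLog:
    """Per-step time series of state, risk and controller case."""

    df: pd.DataFrame
    scenario: str = ""
    meta: dict = dfield(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


def _window_grid(state: VehicleState, t_la: float, cfg: SimConfig) -> FieldGrid:
    fwd = cfg.fwd_factor * state.v * t_la + cfg.fwd_margin
    nx = max(int(math.ceil((fwd + cfg.back_extent) / cfg.grid_delta)), 4)
    ny = max(int(math.ceil(2 * cfg.lat_extent / cfg.grid_delta)), 4)
    c, s = math.cos(state.phi), math.sin(state.phi)
    ox = state.x - cfg.back_extent * c - (-cfg.lat_extent) * s
    oy = state.y - cfg.back_extent * s + (-cfg.lat_extent) * c
    return FieldGrid((ox, oy), cfg.grid_delta, nx, ny, state.phi)


def run(scenario: Scenario, drf: DRFParams = DRFParams(),
        driver: DriverParams = DriverParams(), cfg: SimConfig = SimConfig(),
        spec: VehicleSpec = VehicleSpec()) -> TrajectoryLog:
    """Simulate the closed loop; deterministic for identical inputs."""
    road = scenario.road
    x0, y0 = road.embed(scenario.ego_station, scenario.ego_lat)
    phi0 = wrap_angle(road.heading(scenario.ego_station) + scenario.ego_heading_err)
    state = VehicleState(x0, y0, phi0, scenario.ego_v0, 0.0)
    duration = cfg.duration if cfg.duration is not None else scenario.duration
    n_steps = int(math.ceil(duration / cfg.dt))
    rows = []
    t = 0.0
    for _ in range(n_steps):
        grid = _window_grid(state, drf.t_la, cfg)
        costs = rasterize(scenario, t, grid)
        X, Y = grid.cell_centers()
        fwd = cfg.fwd_factor * state.v * drf.t_la + cfg.fwd_margin
        window = ((state.x, state.y, state.phi, -cfg.back_extent, fwd,
                   cfg.lat_extent) if cfg.horizon_env_penalty else None)
        riskfn = RiskEvaluator(X, Y, costs.values, cfg.grid_delta, state,
                               spec, drf, window=window,
                               c_env=scenario.schema.c_env)
        c_k = riskfn(state.delta)
        dec = decide(state, c_k, riskfn, road, spec, driver, cfg.dt,
                     cfg.literal_step_updates, cfg.delta_max,
                     cfg.avoidance_blend)
        try:
            station, e = road.lane_frame((state.x, state.y))
        except ValueError:
            rows.append({"t": t, "x": state.x, "y": state.y, "phi": state.phi,
                         "v": state.v, "delta": state.delta, "c_k": c_k,
                         "case": "abort", "station": math.nan, "e": math.nan})
            break
        rows.append({"t": t, "x": state.x, "y": state.y, "phi": state.phi,
                     "v": state.v, "delta": state.delta, "c_k": c_k,
                     "case": dec.case, "station": station, "e": e})
        stop = (scenario.stop_station if scenario.stop_station is not None
                else road.length)
        if station >= stop - cfg.end_margin:
            break
        state = step(state, dec.delta_next, dec.v_next, cfg.dt, spec)
        t += cfg.dt
    df = pd.DataFrame(rows, columns=LOG_COLUMNS)
    meta = {
        "scenario": scenario.name,
        "overrides": scenario.meta.get("overrides", {}),
        "drf": asdict(drf),
        "driver": asdict(driver),
        "cfg": {k: v for k, v in asdict(cfg).items()},
        "spec": asdict(spec),
    }
    return TrajectoryLog(df, scenario.name, meta)


# ---------------------------------------------------------------------------
# log persistence: delimited text with a versioned header
# ---------------------------------------------------------------------------


def write_log(log: TrajectoryLog, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {LOG_VERSION}\n")
        fh.write(f"# scenario: {log.scenario}\n")
        fh.write(f"# meta: {json.dumps(log.meta, default=float)}\n")
        fh.write("\t".join(LOG_COLUMNS) + "\n")
        for row in log.df.itertuples(index=False):
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v)
                               for v in row) + "\n")


def read_log(path) -> TrajectoryLog:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].lstrip("# ").strip() != LOG_VERSION:
        raise ValueError(
            f"unsupported log header: expected '# {LOG_VERSION}'")
    scenario, meta, header, data = "", {}, None, []
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith("# scenario:"):
            scenario = line.split(":", 1)[1].strip()
        elif line.startswith("# meta:"):
            meta = json.loads(line.split(":", 1)[1])
        elif line.startswith("#") or not line.strip():
            continue
        elif header is None:
            header = line.split("\t")
            if header != LOG_COLUMNS:
                raise ValueError(f"unexpected column header at line {lineno}")
        else:
            parts = line.split("\t")
            if len(parts) != len(LOG_COLUMNS):
                raise ValueError(
                    f"line {lineno}: expected {len(LOG_COLUMNS)} columns, "
                    f"got {len(parts)}")
            data.append(parts)
    df = pd.DataFrame(data, columns=LOG_COLUMNS)
    if len(df):
        for col in LOG_COLUMNS:
            if col != "case":
                df[col] = df[col].astype(float)
    else:
        df = pd.DataFrame({c: pd.Series(dtype=(object if c == "case" else float))
                           for c in LOG_COLUMNS})
    return TrajectoryLog(df, scenario, meta)
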