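"""Parameter estimation from distance-indexed reference trajectories.

The search objective is the unweighted sum over three signals —
steering angle, speed, lateral deviation, each a function of distance
travelled along the lane centre — of the summed squared model-reference
differences.  Field/driver/scene parameters are estimated by an
exhaustive coarse-to-fine grid search; the desired speed and the
acceleration gain are identified directly from a standing-start run on
an open straight.  A synthetic-reference generator (model output plus
seeded Gaussian noise) stands in for human driving data in recovery
tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dfield, replace

import numpy as np

from .controller import DriverParams
from .field import DRFParams
from .kinematics import VehicleSpec
from .scene import CostSchema, Scenario
from .simulator import SimConfig, TrajectoryLog, run

__all__ = [
    "ReferenceTrajectory",
    "SearchSpace",
    "FitResult",
    "DirectEstimates",
    "objective",
    "direct_estimates",
    "grid_search",
    "synthesize_reference",
    "write_reference",
    "read_reference",
]

log = logging.getLogger(__name__)

DRF_FIELDS = {"p", "t_la", "m", "c", "k1", "k2"}
DRIVER_FIELDS = {"c_t", "v_des", "k_v", "k_vc", "k_h", "t_lah"}
SCHEMA_FIELDS = {"c_road", "c_env", "c_ovt_lane", "c_onc_lane", "c_car"}


@dataclass
class ReferenceTrajectory:
    """Signals indexed by distance along the lane centre."""

    station: np.ndarray
    delta: np.ndarray
    v: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        self.station = np.asarray(self.station, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        if not np.all(np.diff(self.station) > 0):
            raise ValueError("station grid must be strictly increasing")
        for name in ("station", "delta", "v", "e"):
            arr = getattr(self, name)
            if arr.shape != self.station.shape or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and match the station grid")


@dataclass
class SearchSpace:
    """Per-parameter candidate grids plus coarse-to-fine staging."""

    grids: dict  # name -> 1-D array of candidate values
    stages: int = 2
    refine_factor: int = 5

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("search space must contain at least one parameter")
        self.grids = {k: np.atleast_1d(np.asarray(v, dtype=float))
                      for k, v in self.grids.items()}
        for k, g in self.grids.items():
            if g.size == 0:
                raise ValueError(f"empty grid for {k}")
            known = DRF_FIELDS | DRIVER_FIELDS | SCHEMA_FIELDS
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")


@dataclass
class FitResult:
    params: dict
    objective: float
    trace: list  # [(params dict, objective), ...] in evaluation order


@dataclass
class DirectEstimates:
    v_des: float
    k_v: float | None
    identifiable: bool


def _resample(log_: TrajectoryLog, station: np.ndarray):
    df = log_.df
    s = df["station"].to_numpy()
    if s.min() > station[0] + 1e-6 or s.max() < station[-1] - 1e-6:
        raise ValueError(
            f"model log covers stations [{s.min():.1f}, {s.max():.1f}] but the "
            f"reference needs [{station[0]:.1f}, {station[-1]:.1f}]")
    # stations are nondecreasing; make strictly increasing for interp
    s = np.maximum.accumulate(s + np.arange(len(s)) * 1e-12)
    return tuple(np.interp(station, s, df[c].to_numpy())
                 for c in ("delta", "v", "e"))


def objective(model_log: TrajectoryLog, ref: ReferenceTrajectory,
              weights=(1.0, 1.0, 1.0)) -> float:
    """Sum of squared model-reference differences over the three signals.

    Signals are steering, speed and lateral deviation on the reference's
    station grid (model linearly interpolated onto it).  Mixed units are
    summed unweighted by default, exactly as the estimation procedure
    defines; per-signal weights are exposed for sensitivity studies.
    """
    md, mv, me = _resample(model_log, ref.station)
    return float(weights[0] * np.sum((md - ref.delta) ** 2)
                 + weights[1] * np.sum((mv - ref.v) ** 2)
                 + weights[2] * np.sum((me - ref.e) ** 2))


def direct_estimates(straight_run: ReferenceTrajectory,
                     rise_fraction: float = 0.9,
                     plateau_fraction: float = 0.1) -> DirectEstimates:
    """Estimate V_des and k_v from a standing-start run on an open straight.

    V_des is the mean speed over the final ``plateau_fraction`` of the
    run; k_v is the least-squares rate of ``dv/dt = k_v (V_des - v)`` over
    the rising phase (v below ``rise_fraction * V_des``).  A run whose
    speed barely varies leaves k_v unidentifiable (flagged).
    """
    s, v = straight_run.station, straight_run.v
    n_tail = max(int(len(s) * plateau_fraction), 2)
    v_des = float(np.mean(v[-n_tail:]))
    if np.ptp(v) < 0.05 * max(v_des, 1.0):
        return DirectEstimates(v_des, None, False)
    # recover time from the distance grid: dt = ds / v (midpoint speed)
    v_mid = np.maximum(0.5 * (v[1:] + v[:-1]), 1e-3)
    t = np.concatenate([[0.0], np.cumsum(np.diff(s) / v_mid)])
    dvdt = np.gradient(v, t)
    rising = v < rise_fraction * v_des
    if rising.sum() < 3:
        return DirectEstimates(v_des, None, False)
    x = v_des - v[rising]
    y = dvdt[rising]
    k_v = float(np.dot(x, y) / np.dot(x, x))
    return DirectEstimates(v_des, k_v, True)


def _apply_params(params: dict, drf: DRFParams, driver: DriverParams,
                  schema: CostSchema):
    drf_kw = {k: v for k, v in params.items() if k in DRF_FIELDS}
    drv_kw = {k: v for k, v in params.items() if k in DRIVER_FIELDS}
    sch_kw = {k: v for k, v in params.items() if k in SCHEMA_FIELDS}
    return (replace(drf, **drf_kw), replace(driver, **drv_kw),
            replace(schema, **sch_kw))


def grid_search(space: SearchSpace, ref: ReferenceTrajectory,
                scenario: Scenario, drf: DRFParams = DRFParams(),
                driver: DriverParams = DriverParams(),
                cfg: SimConfig = SimConfig(), spec: VehicleSpec = VehicleSpec(),
                runner=None) -> FitResult:
    """Exhaustive coarse-to-fine grid search minimizing :func:`objective`.

    Candidates are evaluated in lexicographic grid order with a
    first-wins tie-break, so the search is deterministic.  Between
    stages each parameter grid is refined by ``refine_factor`` around
    the incumbent, clipped to the original bounds.  A failing candidate
    simulation scores +inf and is logged.
    """
    if runner is None:
        def runner(params: dict) -> TrajectoryLog:
            d, dr, sch = _apply_params(params, drf, driver, scenario.schema)
            sc = replace_schema(scenario, sch)
            return run(sc, d, dr, cfg, spec)

    names = list(space.grids)
    grids = {k: g.copy() for k, g in space.grids.items()}
    bounds = {k: (g.min(), g.max()) for k, g in grids.items()}
    trace: list = []
    best_params, best_obj = None, math.inf
    for stage in range(space.stages):
        for combo in itertools.product(*(grids[k] for k in names)):
            params = dict(zip(names, (float(c) for c in combo)))
            try:
                obj = objective(runner(params), ref)
            except Exception as exc:  # candidate failure -> +inf
                log.warning("candidate %s failed: %s", params, exc)
                obj = math.inf
            trace.append((params, obj))
            if obj < best_obj:  # strict: first-in-order wins ties
                best_params, best_obj = params, obj
        if stage < space.stages - 1 and best_params is not None:
            for k in names:
                g = grids[k]
                if g.size < 2:
                    continue
                step = float(np.min(np.diff(np.sort(g)))) if g.size > 1 else 0.0
                centre = best_params[k]
                fine = np.linspace(centre - step, centre + step,
                                   2 * space.refine_factor + 1)
                lo, hi = bounds[k]
                grids[k] = np.unique(np.clip(fine, lo, hi))
    return FitResult(best_params or {}, best_obj, trace)


def replace_schema(scenario: Scenario, schema: CostSchema) -> Scenario:
    return replace(scenario, schema=schema, meta=dict(scenario.meta))


def synthesize_reference(drf: DRFParams, driver: DriverParams,
                         scenario: Scenario, sigma=(0.0, 0.0, 0.0),
                         seed: int = 0, cfg: SimConfig = SimConfig(),
                         spec: VehicleSpec = VehicleSpec(),
                         spacing: float = 1.0) -> ReferenceTrajectory:
    """Model-generated reference trajectory with additive Gaussian noise.

    Runs the simulator, resamples (steering, speed, lateral deviation)
    onto a ``spacing``-metre station grid, and adds independent noise
    with per-signal standard deviations ``sigma``.  ``sigma = 0`` yields
    the exact model output; the seed makes references reproducible.
    """
    if any(s_ < 0 for s_ in sigma):
        raise ValueError("noise sigmas must be >= 0")
    log_ = run(scenario, drf, driver, cfg, spec)
    s = log_.df["station"].to_numpy()
    station = np.arange(math.ceil(s.min()), math.floor(s.max()) + 1e-9, spacing)
    d, v, e = _resample(log_, station)
    rng = np.random.default_rng(seed)
    d = d + rng.normal(0.0, sigma[0], station.shape)
    v = np.maximum(v + rng.normal(0.0, sigma[1], station.shape), 0.0)
    e = e + rng.normal(0.0, sigma[2], station.shape)
    return ReferenceTrajectory(station, d, v, e)


def write_reference(ref: ReferenceTrajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("# drfsim-ref v1\n")
        fh.write("station\tdelta\tv\te\n")
        for row in zip(ref.station, ref.delta, ref.v, ref.e):
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_reference(path) -> ReferenceTrajectory:
    data = np.loadtxt(path, skiprows=2)
    return ReferenceTrajectory(data[:, 0], data[:, 1], data[:, 2], data[:, 3])
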