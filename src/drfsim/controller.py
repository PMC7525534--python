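"""Perceived risk and the risk-threshold satisficing controller.

The scalar perceived risk ``C`` is the risk field multiplied with the
scene cost map and summed over grid points (a Riemann approximation of
the area integral; see :func:`perceived_risk`).  The driver model keeps
``C`` below an individual threshold ``C_t`` while pursuing a desired
speed ``V_des`` — it *satisfices* rather than optimizes: no corrective
steering is issued as long as risk is acceptable, and corrections are
the minimal ones that restore acceptability.  Four cases arise from
comparing ``C`` with ``C_t`` and ``v`` with ``V_des``; a heading
controller keeps the car aligned with the road whenever risk does not
dictate the steering.

The printed update laws are interpreted as continuous-time rates
(gains multiplied by the integration step), making behaviour
step-size-invariant; the literal per-step form is available through
``literal_step_updates``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import _kernels
from .field import DRFParams, FieldGrid, drf_values
from .kinematics import (
    EPS_STRAIGHT,
    VehicleSpec,
    VehicleState,
    future_pose,
    wrap_angle,
)
from .scene import RoadGeometry

__all__ = [
    "DriverParams",
    "ControlDecision",
    "RiskEvaluator",
    "perceived_risk",
    "heading_steer",
    "minimize_risk_steer",
    "satisficing_steer",
    "decide",
]

log = logging.getLogger(__name__)

#: reference cell size (m) of the risk normalization: C = sum(z*cost) * delta^2
REF_CELL = 1.0


@dataclass(frozen=True)
class DriverParams:
    """Control parameters translating perceived risk into actions.

    c_t : risk threshold below which no corrective action is taken
    v_des : desired free-driving speed, m/s
    k_v : speed-tracking rate gain, 1/s
    k_vc : risk-to-deceleration rate gain, (risk units * s)^-1 m/s^2... rate
    k_h : heading-controller rate gain, 1/s
    t_lah : heading preview time, s
    """

    c_t: float = 3000.0
    v_des: float = 21.6
    k_v: float = 0.14
    k_vc: float = 1.5e-4
    k_h: float = 1.0
    t_lah: float = 1.0

    def __post_init__(self) -> None:
        if not (self.c_t > 0 and self.v_des > 0):
            raise ValueError("c_t and v_des must be > 0")
        for name in ("k_v", "k_vc", "k_h", "t_lah"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ControlDecision:
    case: str  # "1" | "2a" | "2b" | "3" | "4"
    delta_next: float
    v_next: float
    c_k: float
    c_op: float | None = None
    delta_op: float | None = None
    delta_opt: float | None = None


def perceived_risk(field: FieldGrid, costs: FieldGrid) -> float:
    """C = sum(z * cost) * delta^2 over a shared grid.

    The cell-area factor makes C approximate the continuous integral of
    z*cost over the plane, so its value (and hence the thresholds of
    :class:`DriverParams`) is independent of the grid resolution.
    """
    if not field.same_geometry(costs):
        raise ValueError("field and cost map must share the same grid")
    if field.values is None or costs.values is None:
        raise ValueError("both grids must carry values")
    return float(np.sum(field.values * costs.values) * (field.delta / REF_CELL) ** 2)


class RiskEvaluator:
    """Risk as a function of a candidate steering angle at fixed speed.

    Wraps one simulation step's cost map (flat world-coordinate arrays)
    and the current vehicle state; calling it with ``delta`` evaluates
    the risk the field would accrue under that steering.  Parts of the
    predicted path that leave the rasterized window are charged the
    environment cost via a 1-m line quadrature of the field's transverse
    mass, so steering the field out of the window is never mistaken for
    safety.
    """

    def __init__(self, X, Y, cost, cell, state: VehicleState,
                 spec: VehicleSpec, params: DRFParams,
                 window=None, c_env: float = 0.0, horizon_ds: float = 1.0):
        self.X = np.ascontiguousarray(X, dtype=float).ravel()
        self.Y = np.ascontiguousarray(Y, dtype=float).ravel()
        self.cost = np.ascontiguousarray(cost, dtype=float).ravel()
        self.cell = float(cell)
        self.state = state
        self.spec = spec
        self.params = params
        self.window = window  # (x0, y0, theta, u_lo, u_hi, v_abs) or None
        self.c_env = c_env
        self.horizon_ds = horizon_ds

    def __call__(self, delta: float) -> float:
        if abs(delta) >= math.pi / 2 - 1e-9:
            return math.inf  # beyond steering lock the bicycle model degenerates
        st, p = self.state, self.params
        total = _kernels.risk_sum(
            self.X, self.Y, self.cost, st.x, st.y, st.phi, st.v, float(delta),
            self.spec.wheelbase, p.p, p.t_la, p.m, p.c, p.k1, p.k2,
            EPS_STRAIGHT,
        ) * (self.cell / REF_CELL) ** 2
        if self.window is not None and self.c_env > 0.0:
            total += self._horizon_penalty(float(delta))
        return total

    def _horizon_penalty(self, delta: float) -> float:
        st, p = self.state, self.params
        smax = st.v * p.t_la
        if smax <= 0.0:
            return 0.0
        ds = self.horizon_ds
        s = np.arange(0.5 * ds, smax, ds)
        probe = VehicleState(st.x, st.y, st.phi, max(st.v, 1e-9), delta)
        t = s / probe.v
        # sample path points (vectorized closed form, mirrors future_pose)
        if abs(delta) < EPS_STRAIGHT:
            px = st.x + s * math.cos(st.phi)
            py = st.y + s * math.sin(st.phi)
        else:
            sgn = 1.0 if delta > 0 else -1.0
            R = self.spec.wheelbase / math.tan(abs(delta))
            xc = st.x + sgn * R * (-math.sin(st.phi))
            yc = st.y + sgn * R * math.cos(st.phi)
            dth = sgn * s / R
            dx, dy = st.x - xc, st.y - yc
            px = xc + np.cos(dth) * dx - np.sin(dth) * dy
            py = yc + np.sin(dth) * dx + np.cos(dth) * dy
        x0, y0, th, u_lo, u_hi, v_abs = self.window
        c, s_ = math.cos(th), math.sin(th)
        u = (px - x0) * c + (py - y0) * s_
        v = -(px - x0) * s_ + (py - y0) * c
        outside = (u < u_lo) | (u > u_hi) | (np.abs(v) > v_abs)
        if not np.any(outside):
            return 0.0
        a = p.p * (s[outside] - smax) ** 2
        ad = abs(delta)
        sig = ((p.m + p.k1 * ad) + (p.m + p.k2 * ad)) * s[outside] + 2 * p.c
        return float(np.sum(a * math.sqrt(math.pi / 2) * sig * self.c_env * ds))


def heading_steer(state: VehicleState, spec: VehicleSpec, road: RoadGeometry,
                  params: DriverParams, dt: float,
                  literal_step_updates: bool = False) -> float:
    """Heading-alignment steering: nudge delta toward the road heading.

    Both the car heading and the road heading are taken ``t_lah`` seconds
    in the future, the car's from the predicted path, the road's at the
    future pose's station.
    """
    fx, fy, fphi = future_pose(state, spec, params.t_lah)
    try:
        station, _e, ok = road.lane_frame_arrays(np.asarray([fx]), np.asarray([fy]))
        if not ok[0]:
            raise ValueError("future pose off the road corridor")
        phi_road = road.heading(float(station[0]))
    except ValueError:
        log.warning("heading controller: future pose not projectable; holding delta")
        return state.delta
    gain = params.k_h * (1.0 if literal_step_updates else dt)
    return state.delta + gain * wrap_angle(phi_road - fphi)


def minimize_risk_steer(riskfn, delta_k: float, bounds=None,
                        coarse: float = 0.1, xatol: float = 1e-3):
    """Globally minimize risk over steering within ``delta_k +- pi``.

    Deterministic coarse sweep followed by bounded local refinement;
    guarantees ``C_op <= C(delta_k)`` since ``delta_k`` is a candidate.
    Returns ``(delta_op, c_op)``.
    """
    lo, hi = bounds if bounds is not None else (delta_k - math.pi, delta_k + math.pi)
    n = max(int(math.ceil((hi - lo) / coarse)) + 1, 3)
    # coarse sweep over the full bounds (inclusive symmetric endpoints keep
    # the search mirror-equivariant), plus a fine sweep at resolution xatol
    # around the current steering: the useful minima — gentle sidesteps,
    # curve tracking — are milliradian-scale basins that hug delta_k, which
    # a coarse grid straddles and a golden-section bracket is not unimodal
    # over
    grid = np.linspace(lo, hi, n)
    fine = delta_k + np.arange(-20, 21) * (2 * xatol)
    grid = np.unique(np.concatenate(
        [grid, fine[(fine >= lo) & (fine <= hi)], [delta_k]]))
    vals = np.array([riskfn(d) for d in grid])
    i = int(np.argmin(vals))
    best_d, best_c = float(grid[i]), float(vals[i])
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, len(grid) - 1)]
    if bhi > blo:
        res = minimize_scalar(riskfn, bounds=(blo, bhi), method="bounded",
                              options={"xatol": xatol})
        if res.fun <= best_c:
            best_d, best_c = float(res.x), float(res.fun)
    c_k = float(riskfn(delta_k))
    if c_k < best_c:  # never worse than staying put
        best_d, best_c = delta_k, c_k
    return best_d, best_c


def satisficing_steer(riskfn, delta_k: float, delta_op: float, c_t: float,
                      n_march: int = 24, xtol: float = 1e-3) -> float:
    """Minimal steering correction bringing risk down to the threshold.

    Root of ``C(delta) = c_t`` on the segment between ``delta_k`` (where
    C > c_t) and ``delta_op`` (where C < c_t), closest to ``delta_k`` —
    the model corrects just enough, it does not over-correct toward the
    risk minimum.
    """
    if riskfn(delta_k) <= c_t:
        return delta_k
    ts = np.linspace(delta_k, delta_op, n_march + 1)
    prev = ts[0]
    for d in ts[1:]:
        if riskfn(d) < c_t:
            if abs(d - prev) <= xtol:
                return float(d)
            return float(brentq(lambda x: riskfn(x) - c_t, prev, d, xtol=xtol))
        prev = d
    log.warning("satisficing_steer: no crossing found on segment; using delta_op")
    return delta_op


def decide(state: VehicleState, c_k: float, riskfn, road: RoadGeometry,
           spec: VehicleSpec, driver: DriverParams, dt: float,
           literal_step_updates: bool = False,
           delta_max: float | None = math.pi / 4,
           avoidance_blend: float = 0.08) -> ControlDecision:
    """One satisficing control decision (the four-case algorithm).

    case 1 (C < C_t, v < V_des): accelerate toward V_des, steer by heading.
    case 2 (C > C_t, v < V_des): find risk-minimizing steering delta_op;
        2a if its risk clears the threshold, apply only the minimal
        correction delta_opt and keep accelerating;
        2b otherwise brake proportional to the steering relief C_op - C_k
        while steering from the heading baseline a bounded fraction
        (``avoidance_blend``) toward delta_op.
    case 3 (C < C_t, v > V_des): decelerate toward V_des, steer by heading.
    case 4 (C > C_t, v > V_des): brake proportional to C_t - C_k plus the
        speed-tracking term, steering as in 2b.

    In cases 2b/4 the heading controller anchors the steering: if the
    commanded steering tracked delta_op outright, the relief term would
    collapse to zero (no braking) and the accumulated marginal sidesteps
    would creep the car around obstacles it should brake for; the bounded
    blend preserves the braking signal while still yielding laterally to
    threats that steering can genuinely mitigate.

    Equality boundaries are folded into the "<" branches.
    """
    f = 1.0 if literal_step_updates else dt
    v, delta_op, c_op, delta_opt = state.v, None, None, None
    risky = c_k > driver.c_t
    lock = math.pi / 2 - 1e-6
    dmax = min(delta_max, lock) if delta_max is not None else lock
    opt_bounds = (max(state.delta - math.pi, -dmax),
                  min(state.delta + math.pi, dmax))
    if not risky:
        case = "1" if v <= driver.v_des else "3"
        delta_next = heading_steer(state, spec, road, driver, dt,
                                   literal_step_updates)
        v_next = v + f * driver.k_v * (driver.v_des - v)
    elif v <= driver.v_des:
        delta_op, c_op = minimize_risk_steer(riskfn, state.delta, opt_bounds)
        if c_op < driver.c_t:
            case = "2a"
            delta_opt = satisficing_steer(riskfn, state.delta, delta_op,
                                          driver.c_t)
            delta_next = delta_opt
            v_next = v + f * driver.k_v * (driver.v_des - v)
        else:
            case = "2b"
            head = heading_steer(state, spec, road, driver, dt,
                                 literal_step_updates)
            delta_next = head + avoidance_blend * (delta_op - head)
            v_next = v + f * driver.k_vc * (c_op - c_k)
    else:
        case = "4"
        delta_op, c_op = minimize_risk_steer(riskfn, state.delta, opt_bounds)
        head = heading_steer(state, spec, road, driver, dt,
                             literal_step_updates)
        delta_next = head + avoidance_blend * (delta_op - head)
        v_next = (v + f * driver.k_vc * (driver.c_t - c_k)
                  + f * driver.k_v * (driver.v_des - v))
    if delta_max is not None:
        delta_next = float(np.clip(delta_next, -delta_max, delta_max))
    return ControlDecision(case, float(delta_next), max(float(v_next), 0.0),
                           c_k, c_op, delta_op, delta_opt)
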