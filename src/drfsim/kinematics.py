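"""Kinematic bicycle model and the constant-control predicted path.

The vehicle is a kinematic bicycle: with steering angle ``delta`` held
constant it travels a circular arc of radius ``R = L / tan(|delta|)``
(wheelbase ``L``), to the left for positive ``delta``.  The *predicted
path* is this arc (or a ray, for straight driving), truncated at the
look-ahead distance ``v * t_la``.  Both the risk field and the heading
controller are built on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "VehicleSpec",
    "VehicleState",
    "PredictedPath",
    "EPS_STRAIGHT",
    "wrap_angle",
    "turning_radius",
    "predicted_path",
    "project_point",
    "future_pose",
    "step",
]

#: below this |steering angle| (rad) the path is treated as a straight ray
EPS_STRAIGHT = 1e-6


def wrap_angle(a):
    """Wrap an angle (scalar or array) to (-pi, pi]."""
    out = np.remainder(np.asarray(a) + np.pi, 2.0 * np.pi)
    out = np.where(out <= 0.0, out + 2.0 * np.pi, out) - np.pi
    if np.ndim(a) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class VehicleSpec:
    """Physical dimensions of a car (metres)."""

    width: float = 2.0
    length: float = 5.0
    wheelbase: float = 2.9

    def __post_init__(self) -> None:
        for name in ("width", "length", "wheelbase"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"VehicleSpec.{name} must be finite and > 0, got {v}")
        if self.wheelbase >= self.length:
            raise ValueError("wheelbase must be smaller than overall length")


@dataclass(frozen=True)
class VehicleState:
    """Pose, speed and steering of the ego car at one instant.

    ``phi`` is the heading in radians, CCW from +x, wrapped to (-pi, pi];
    positive ``delta`` steers left.
    """

    x: float
    y: float
    phi: float
    v: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "phi", "v", "delta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"VehicleState.{name} must be finite")
        if self.v < 0:
            raise ValueError(f"speed must be >= 0, got {self.v}")
        object.__setattr__(self, "phi", wrap_angle(self.phi))


@dataclass(frozen=True)
class PredictedPath:
    """Constant-control arc (or straight ray) from the current pose.

    For an arc the centre sits at distance ``R`` perpendicular to the
    heading, on the turn side; ``s_max = v * t_la`` is the arc-length
    support of the risk field.
    """

    kind: str  # "arc" | "straight"
    x0: float
    y0: float
    phi: float
    s_max: float
    R: float = math.inf
    xc: float = math.nan
    yc: float = math.nan
    turn_sense: str = "none"  # "left" | "right" | "none"


def turning_radius(delta: float, L: float):
    """Turning radius of the kinematic bicycle, ``R = L / tan(|delta|)``.

    Returns ``(R, sense)`` where ``sense`` is ``"left"``/``"right"``; for
    |delta| below :data:`EPS_STRAIGHT` returns ``(inf, "none")`` (straight).
    """
    if not (math.isfinite(delta) and math.isfinite(L)):
        raise ValueError("delta and L must be finite")
    if L <= 0:
        raise ValueError(f"wheelbase must be > 0, got {L}")
    if abs(delta) < EPS_STRAIGHT:
        return math.inf, "none"
    return L / math.tan(abs(delta)), ("left" if delta > 0 else "right")


def predicted_path(state: VehicleState, spec: VehicleSpec, t_la: float) -> PredictedPath:
    """Predicted path under constant steering and speed for ``t_la`` seconds."""
    if not t_la > 0:
        raise ValueError(f"t_la must be > 0, got {t_la}")
    s_max = state.v * t_la
    R, sense = turning_radius(state.delta, spec.wheelbase)
    if sense == "none":
        return PredictedPath("straight", state.x, state.y, state.phi, s_max)
    sgn = 1.0 if sense == "left" else -1.0
    # left normal of heading phi is (-sin phi, cos phi)
    xc = state.x + sgn * R * (-math.sin(state.phi))
    yc = state.y + sgn * R * math.cos(state.phi)
    return PredictedPath("arc", state.x, state.y, state.phi, s_max, R, xc, yc, sense)


def project_point(path: PredictedPath, p):
    """Project a point onto the path.

    Returns ``(s, d, side)``: arc length from the path origin in the
    direction of travel, unsigned lateral offset, and which side of the
    path the point lies on (``"inner"`` toward the turn centre, ``"outer"``
    away; for straight paths the left side maps to "inner", which is
    immaterial since the width law loses its side dependence at delta = 0).
    Points behind the origin have ``s < 0`` (straight paths only; arc
    arc-lengths are wrapped to [0, 2*pi*R)).
    """
    px, py = float(p[0]), float(p[1])
    if path.kind == "straight":
        dx, dy = px - path.x0, py - path.y0
        c, s_ = math.cos(path.phi), math.sin(path.phi)
        lon = dx * c + dy * s_
        lat = -dx * s_ + dy * c
        return lon, abs(lat), ("inner" if lat >= 0 else "outer")
    sgn = 1.0 if path.turn_sense == "left" else -1.0
    dist = math.hypot(px - path.xc, py - path.yc)
    d = abs(dist - path.R)
    th_p = math.atan2(py - path.yc, px - path.xc)
    th_0 = math.atan2(path.y0 - path.yc, path.x0 - path.xc)
    dth = sgn * (th_p - th_0)
    dth %= 2.0 * math.pi
    return path.R * dth, d, ("inner" if dist < path.R else "outer")


def future_pose(state: VehicleState, spec: VehicleSpec, t: float):
    """Pose ``(x, y, phi)`` after travelling ``v * t`` along the predicted path."""
    if t < 0:
        raise ValueError("t must be >= 0")
    s = state.v * t
    R, sense = turning_radius(state.delta, spec.wheelbase)
    if sense == "none":
        return (
            state.x + s * math.cos(state.phi),
            state.y + s * math.sin(state.phi),
            state.phi,
        )
    sgn = 1.0 if sense == "left" else -1.0
    dth = sgn * s / R
    xc = state.x + sgn * R * (-math.sin(state.phi))
    yc = state.y + sgn * R * math.cos(state.phi)
    # rotate the origin about the centre by dth
    c, s_ = math.cos(dth), math.sin(dth)
    dx, dy = state.x - xc, state.y - yc
    return (
        xc + c * dx - s_ * dy,
        yc + s_ * dx + c * dy,
        wrap_angle(state.phi + dth),
    )


def step(state: VehicleState, delta_next: float, v_next: float, dt: float,
         spec: VehicleSpec) -> VehicleState:
    """Forward-Euler update of the kinematic bicycle with the new controls.

    ``x' = v cos(phi)``, ``y' = v sin(phi)``, ``phi' = v tan(delta)/L``,
    evaluated at the current state; the new controls are stored in the
    returned state.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if v_next < 0:
        raise ValueError("v_next must be >= 0")
    L = spec.wheelbase
    x = state.x + dt * state.v * math.cos(state.phi)
    y = state.y + dt * state.v * math.sin(state.phi)
    phi = wrap_angle(state.phi + dt * state.v * math.tan(state.delta) / L)
    return VehicleState(x, y, phi, v_next, delta_next)
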