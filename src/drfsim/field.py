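"""The Driver's Risk Field (DRF).

The field ``z(x, y)`` encodes the driver's subjective probability of
occupying a position within the next ``t_la`` seconds.  It is a torus
bent along the predicted path with a Gaussian cross-section:

    z = a(s) * exp(-d^2 / (2 * sigma_side(s)^2))

where ``s`` is arc length along the predicted path and ``d`` the offset
from it.  The height is a parabola rooted at the look-ahead distance,
``a(s) = p * (s - v*t_la)^2`` on ``s in [0, v*t_la]`` and zero outside
(the field only extends ahead of the car).  The half-width grows
linearly with arc length and with |steering angle|,

    sigma_i(s) = (m + k_i * |delta|) * s + c,   i = inner, outer,

mirroring signal-dependent noise in human motor control: command
variability grows with command magnitude.  ``k_inner < k_outer`` makes
the field asymmetric, which is what lets the model cut corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from .kinematics import (
    EPS_STRAIGHT,
    PredictedPath,
    VehicleSpec,
    VehicleState,
    predicted_path,
    turning_radius,
)

__all__ = ["DRFParams", "FieldGrid", "height_at", "width_at", "evaluate", "drf_values"]

#: maximum admissible |steering angle| used when validating parameter sets
DELTA_MAX = math.pi / 4


@dataclass(frozen=True)
class DRFParams:
    """Six shape parameters of the risk field.

    p : steepness of the height parabola
    t_la : look-ahead (preview) time, s
    m : width slope at zero steering (dimensionless)
    c : half-width at the car, m (car-width/4, so +-2 sigma covers ~95%)
    k1, k2 : inner/outer width gain per radian of steering
    """

    p: float = 0.0064
    t_la: float = 3.5
    m: float = 0.001
    c: float = 0.5
    k1: float = 0.0
    k2: float = 1.3823

    def __post_init__(self) -> None:
        if not self.t_la > 0:
            raise ValueError("t_la must be > 0")
        if not self.c > 0:
            raise ValueError("c must be > 0")
        if self.p < 0:
            raise ValueError("p must be >= 0")
        # sigma must stay positive over the support for admissible steering
        s_probe = 100.0
        for k in (self.k1, self.k2):
            if (self.m + k * DELTA_MAX) * s_probe + self.c <= 0 and (self.m + k * DELTA_MAX) < 0:
                # negative slope: find where it crosses zero; reject if within probe range
                raise ValueError(
                    "width sigma becomes non-positive within the field support "
                    f"for |delta| = {DELTA_MAX:.3f} (m={self.m}, k={k}, c={self.c})"
                )


@dataclass
class FieldGrid:
    """Rectangular evaluation grid, optionally rotated by ``theta``.

    Cell centres are at ``origin + (i + 0.5) * delta`` along the grid axes,
    the grid x-axis making angle ``theta`` with world +x.  ``values`` holds
    per-cell field heights (or costs) with shape ``(ny, nx)``.
    """

    origin: tuple[float, float]
    delta: float
    nx: int
    ny: int
    theta: float = 0.0
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("cell size delta must be > 0")
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid counts must be positive")

    def cell_centers(self):
        """World coordinates of all cell centres, two (ny, nx) arrays."""
        iu = (np.arange(self.nx) + 0.5) * self.delta
        iv = (np.arange(self.ny) + 0.5) * self.delta
        U, V = np.meshgrid(iu, iv)
        c, s = math.cos(self.theta), math.sin(self.theta)
        X = self.origin[0] + U * c - V * s
        Y = self.origin[1] + U * s + V * c
        return X, Y

    def copy_empty(self) -> "FieldGrid":
        return FieldGrid(self.origin, self.delta, self.nx, self.ny, self.theta)

    def same_geometry(self, other: "FieldGrid") -> bool:
        return (
            np.allclose(self.origin, other.origin)
            and self.delta == other.delta
            and self.nx == other.nx
            and self.ny == other.ny
            and np.isclose(self.theta, other.theta)
        )


def height_at(s, v: float, params: DRFParams):
    """Gaussian height ``a(s) = p (s - v t_la)^2`` clamped to the support.

    Zero for ``s`` outside ``[0, v*t_la]``: the field only extends ahead of
    the vehicle, and the parabola is only meaningful up to its root.
    """
    s = np.asarray(s, dtype=float)
    smax = v * params.t_la
    a = params.p * (s - smax) ** 2
    out = np.where((s >= 0.0) & (s <= smax), a, 0.0)
    return float(out) if out.ndim == 0 else out


def width_at(s, delta: float, side: str, params: DRFParams):
    """Gaussian half-width ``sigma_i(s) = (m + k_i |delta|) s + c``."""
    s = np.asarray(s, dtype=float)
    k = params.k1 if side == "inner" else params.k2
    sigma = (params.m + k * abs(delta)) * s + params.c
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive over the requested arc lengths")
    return float(sigma) if sigma.ndim == 0 else sigma


def drf_values(X, Y, state: VehicleState, spec: VehicleSpec, params: DRFParams):
    """Field height ``z`` at world points ``(X, Y)`` (vectorized).

    Straight-line degenerate geometry is used below ``EPS_STRAIGHT``;
    out-of-support points (behind the car, beyond the look-ahead distance,
    or past the swept angle of a tight arc) are exactly zero.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    smax = state.v * params.t_la
    if smax <= 0.0:
        return np.zeros(np.broadcast(X, Y).shape)
    adelta = abs(state.delta)
    R, sense = turning_radius(state.delta, spec.wheelbase)
    if sense == "none":
        c, s_ = math.cos(state.phi), math.sin(state.phi)
        dx, dy = X - state.x, Y - state.y
        s = dx * c + dy * s_
        lat = -dx * s_ + dy * c
        d = np.abs(lat)
        inner = lat >= 0
    else:
        sgn = 1.0 if sense == "left" else -1.0
        xc = state.x + sgn * R * (-math.sin(state.phi))
        yc = state.y + sgn * R * math.cos(state.phi)
        dist = np.hypot(X - xc, Y - yc)
        d = np.abs(dist - R)
        th0 = math.atan2(state.y - yc, state.x - xc)
        dth = sgn * (np.arctan2(Y - yc, X - xc) - th0)
        dth = np.remainder(dth, 2.0 * math.pi)
        s = R * dth
        inner = dist < R
    support = (s >= 0.0) & (s <= smax)
    a = params.p * (s - smax) ** 2
    k_side = np.where(inner, params.k1, params.k2)
    sigma = (params.m + k_side * adelta) * s + params.c
    z = np.zeros_like(a)
    np.copyto(z, a * np.exp(-0.5 * (d / sigma) ** 2), where=support & (sigma > 0))
    return z


def evaluate(state: VehicleState, spec: VehicleSpec, params: DRFParams,
             grid: FieldGrid) -> FieldGrid:
    """Evaluate the risk field over ``grid``; returns a grid with ``values`` set."""
    X, Y = grid.cell_centers()
    out = grid.copy_empty()
    out.values = drf_values(X, Y, state, spec, params)
    return out
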