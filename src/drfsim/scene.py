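"""Roads, lanes, obstacles and their rasterization into cost maps.

A road is an ordered chain of straight and arc segments (G1-continuous
by construction); positions are described in the *lane frame* (station
along the ego-lane centreline, signed lateral deviation, positive to the
left of travel).  Lane-type bands (ego / overtake / oncoming) assign the
consequence cost of occupying each lateral strip, obstacle cars override
them, and everything outside the road corridor carries the environment
cost.  The seven study scenarios plus a concatenated full track are
exposed through :func:`build_scenario`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dfield, replace

import numpy as np

from .field import FieldGrid
from .kinematics import VehicleSpec, wrap_angle

__all__ = [
    "CostSchema",
    "Straight",
    "Arc",
    "RoadGeometry",
    "LaneBand",
    "Obstacle",
    "Scenario",
    "rasterize",
    "lane_frame",
    "build_scenario",
    "SCENARIO_NAMES",
]

log = logging.getLogger(__name__)

#: obstacle/traffic sedan footprint (m)
SEDAN_WIDTH = 1.8
SEDAN_LENGTH = 5.0


@dataclass(frozen=True)
class CostSchema:
    """Consequence cost of occupying each element of the driving scene."""

    c_road: float = 0.0
    c_env: float = 500.0
    c_ovt_lane: float = 3.5
    c_onc_lane: float = 14.0  # four times as dangerous as the overtake lane
    c_car: float = 2500.0

    def __post_init__(self) -> None:
        for name in ("c_road", "c_env", "c_ovt_lane", "c_onc_lane", "c_car"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def of(self, kind: str) -> float:
        return {
            "ego": self.c_road,
            "overtake": self.c_ovt_lane,
            "oncoming": self.c_onc_lane,
            "env": self.c_env,
            "car": self.c_car,
        }[kind]


@dataclass(frozen=True)
class Straight:
    length: float


@dataclass(frozen=True)
class Arc:
    radius: float
    sweep: float  # signed, rad; positive = left turn

    @property
    def length(self) -> float:
        return self.radius * abs(self.sweep)


class RoadGeometry:
    """Chain of segments defining the ego-lane centreline."""

    def __init__(self, segments, lane_width: float = 3.5,
                 start_pose=(0.0, 0.0, 0.0)):
        if not segments:
            raise ValueError("road needs at least one segment")
        if lane_width <= 0:
            raise ValueError("lane width must be positive")
        self.segments = list(segments)
        self.lane_width = float(lane_width)
        # cumulative start pose and station of each segment
        self._starts = []
        x, y, th = start_pose
        s0 = 0.0
        for seg in self.segments:
            self._starts.append((x, y, th, s0))
            if isinstance(seg, Straight):
                x += seg.length * math.cos(th)
                y += seg.length * math.sin(th)
            else:
                sgn = 1.0 if seg.sweep > 0 else -1.0
                xc = x + sgn * seg.radius * (-math.sin(th))
                yc = y + sgn * seg.radius * math.cos(th)
                dth = seg.sweep
                c, s_ = math.cos(dth), math.sin(dth)
                dx, dy = x - xc, y - yc
                x = xc + c * dx - s_ * dy
                y = yc + s_ * dx + c * dy
                th = wrap_angle(th + dth)
            s0 += seg.length
        self.length = s0

    # -- forward map ---------------------------------------------------
    def frame(self, station: float):
        """Centreline pose ``(x, y, heading)`` at a station (clamped to the road)."""
        station = min(max(station, 0.0), self.length)
        for seg, (x, y, th, s0) in zip(self.segments, self._starts):
            if station <= s0 + seg.length + 1e-9:
                u = station - s0
                if isinstance(seg, Straight):
                    return (x + u * math.cos(th), y + u * math.sin(th), th)
                sgn = 1.0 if seg.sweep > 0 else -1.0
                xc = x + sgn * seg.radius * (-math.sin(th))
                yc = y + sgn * seg.radius * math.cos(th)
                dth = sgn * u / seg.radius
                c, s_ = math.cos(dth), math.sin(dth)
                dx, dy = x - xc, y - yc
                return (xc + c * dx - s_ * dy, yc + s_ * dx + c * dy,
                        wrap_angle(th + dth))
        x, y, th, _ = self._starts[-1]
        return (x, y, th)

    def heading(self, station: float) -> float:
        return self.frame(station)[2]

    def embed(self, station: float, e: float):
        """World point at (station, lateral offset e); e > 0 is left of travel."""
        x, y, th = self.frame(station)
        return (x - e * math.sin(th), y + e * math.cos(th))

    # -- inverse map ---------------------------------------------------
    def lane_frame_arrays(self, X, Y):
        """Vectorized inverse map: world points -> (station, e, valid).

        Points that project onto no segment (beyond the road ends, or
        outside an arc's angular wedge) are flagged invalid; where several
        segments are candidates (near joints, overlapping wedges) the one
        with the smallest |e| wins.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        best_e = np.full(X.shape, np.inf)
        best_s = np.full(X.shape, np.nan)
        valid = np.zeros(X.shape, dtype=bool)
        tol = 1e-9
        for seg, (x0, y0, th, s0) in zip(self.segments, self._starts):
            if isinstance(seg, Straight):
                c, s_ = math.cos(th), math.sin(th)
                dx, dy = X - x0, Y - y0
                u = dx * c + dy * s_
                e = -dx * s_ + dy * c
                ok = (u >= -tol) & (u <= seg.length + tol)
            else:
                sgn = 1.0 if seg.sweep > 0 else -1.0
                xc = x0 + sgn * seg.radius * (-math.sin(th))
                yc = y0 + sgn * seg.radius * math.cos(th)
                r = np.hypot(X - xc, Y - yc)
                e = sgn * (seg.radius - r)
                th0 = math.atan2(y0 - yc, x0 - xc)
                dth = (sgn * (np.arctan2(Y - yc, X - xc) - th0)) % (2.0 * math.pi)
                u = seg.radius * dth
                ok = u <= seg.length + tol
            better = ok & (np.abs(e) < np.abs(best_e))
            best_e = np.where(better, e, best_e)
            best_s = np.where(better, s0 + np.clip(u, 0.0, seg.length), best_s)
            valid |= ok
        return best_s, best_e, valid

    def lane_frame(self, p):
        """Single-point inverse map -> (station, e). Raises outside the corridor."""
        s, e, ok = self.lane_frame_arrays(
            np.asarray([p[0]]), np.asarray([p[1]]))
        if not ok[0]:
            raise ValueError(f"point {p} does not project onto the road")
        return float(s[0]), float(e[0])


def lane_frame(road: RoadGeometry, p):
    """Module-level convenience wrapper of :meth:`RoadGeometry.lane_frame`."""
    return road.lane_frame(p)


@dataclass(frozen=True)
class LaneBand:
    """Lateral strip [e_lo, e_hi) of lane type ``kind`` over a station range."""

    kind: str  # "ego" | "overtake" | "oncoming"
    e_lo: float
    e_hi: float
    s_lo: float = 0.0
    s_hi: float = math.inf


@dataclass(frozen=True)
class Obstacle:
    """Rectangular car footprint anchored in the lane frame.

    ``speed`` is signed along increasing station; oncoming cars have
    negative speed and face backwards.  ``station0`` is the footprint
    centre at t = 0.
    """

    station0: float
    lat: float
    speed: float = 0.0
    width: float = SEDAN_WIDTH
    length: float = SEDAN_LENGTH

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("obstacle footprint must be positive")

    def station_at(self, t: float) -> float:
        return self.station0 + self.speed * t

    def pose_at(self, road: RoadGeometry, t: float):
        s = self.station_at(t)
        x, y = road.embed(s, self.lat)
        th = road.heading(s)
        if self.speed < 0:
            th = wrap_angle(th + math.pi)
        return x, y, th


@dataclass
class Scenario:
    name: str
    road: RoadGeometry
    bands: list
    obstacles: list
    schema: CostSchema
    ego_station: float = 0.0
    ego_lat: float = 0.0
    ego_v0: float = 18.0
    ego_heading_err: float = 0.0
    duration: float = 60.0
    stop_station: float | None = None  # None -> end of road geometry
    meta: dict = dfield(default_factory=dict)


def rasterize(scenario: Scenario, t: float, grid: FieldGrid) -> FieldGrid:
    """Cost of the driving scene at time ``t`` on ``grid`` (cell-centre test).

    Priority: car footprints > lane bands > environment.
    """
    X, Y = grid.cell_centers()
    S, E, valid = scenario.road.lane_frame_arrays(X, Y)
    cost = np.full(X.shape, scenario.schema.c_env)
    for band in scenario.bands:
        m = (valid & (S >= band.s_lo) & (S <= band.s_hi)
             & (E >= band.e_lo) & (E < band.e_hi))
        cost[m] = scenario.schema.of(band.kind)
    for obs in scenario.obstacles:
        ox, oy, oth = obs.pose_at(scenario.road, t)
        # cheap reject: obstacle far outside this grid window
        gx, gy = grid.origin
        diag = grid.delta * math.hypot(grid.nx, grid.ny)
        if math.hypot(ox - gx, oy - gy) > diag + obs.length:
            continue
        c, s_ = math.cos(oth), math.sin(oth)
        du = (X - ox) * c + (Y - oy) * s_
        dv = -(X - ox) * s_ + (Y - oy) * c
        m = (np.abs(du) <= obs.length / 2) & (np.abs(dv) <= obs.width / 2)
        cost[m] = scenario.schema.c_car
    out = grid.copy_empty()
    out.values = cost
    return out


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

SCENARIO_NAMES = (
    "curve_radius",
    "lane_width",
    "obstacle",
    "furniture",
    "car_following",
    "overtaking",
    "oncoming",
    "full_track",
)


def _ego_band(w: float, s_lo=0.0, s_hi=math.inf):
    return LaneBand("ego", -w / 2, w / 2, s_lo, s_hi)


def _build_curve_radius(R=200.0, lane_width=3.5, entry=150.0, exit_len=100.0,
                        sweep_deg=45.0, direction="left", v0=19.0,
                        runout=150.0, **_):
    sweep = math.radians(sweep_deg) * (1 if direction == "left" else -1)
    road = RoadGeometry(
        [Straight(entry), Arc(R, sweep), Straight(exit_len + runout)],
        lane_width)
    arc_len = R * abs(sweep)
    stop = entry + arc_len + exit_len
    meta = {
        "curve": {"s_lo": entry, "s_hi": entry + arc_len, "R": R,
                  "direction": direction, "lane_width": lane_width},
    }
    return Scenario("curve_radius", road, [_ego_band(lane_width)], [],
                    CostSchema(), ego_v0=v0, stop_station=stop,
                    duration=stop / 6.0 + 20.0, meta=meta)


def _build_lane_width(w=3.5, length=500.0, v0=18.0,
                      heading_err=math.radians(2.0), runout=150.0,
                      duration=None, **_):
    road = RoadGeometry([Straight(length + runout)], w)
    meta = {"steady": {"s_lo": 150.0, "s_hi": length - 20.0}}
    return Scenario("lane_width", road, [_ego_band(w)], [], CostSchema(),
                    ego_v0=v0, ego_heading_err=heading_err,
                    duration=duration or length / 8.0 + 20.0,
                    stop_station=length, meta=meta)


def _build_obstacle(encroachment=0.9, lane_width=3.5, length=400.0,
                    obs_station=250.0, v0=18.0, **_):
    if encroachment > lane_width:
        raise ValueError("encroachment cannot exceed the lane width")
    road = RoadGeometry([Straight(length + 150.0)], lane_width)
    # parked on the left edge: inner edge of the car lies `encroachment`
    # metres inside the lane boundary
    lat = lane_width / 2 - encroachment + SEDAN_WIDTH / 2
    obs = Obstacle(obs_station, lat, 0.0)
    meta = {"obstacle_station": obs_station, "encroachment": encroachment}
    return Scenario("obstacle", road, [_ego_band(lane_width)], [obs],
                    CostSchema(), ego_v0=v0, duration=length / 7.0 + 15.0,
                    stop_station=length, meta=meta)


def _build_furniture(symmetric=False, lane_width=3.5, length=550.0,
                     row_start=200.0, row_length=200.0, n_cars=10,
                     clearance=1.0, v0=18.0, **_):
    road = RoadGeometry([Straight(length + 150.0)], lane_width)
    lat = lane_width / 2 + clearance  # car centre outside the boundary
    stations = np.linspace(row_start, row_start + row_length, n_cars)
    obstacles = [Obstacle(float(s), lat) for s in stations]
    if symmetric:
        obstacles += [Obstacle(float(s), -lat) for s in stations]
    meta = {"row": {"s_lo": row_start, "s_hi": row_start + row_length},
            "symmetric": symmetric}
    return Scenario("furniture", road, [_ego_band(lane_width)], obstacles,
                    CostSchema(), ego_v0=v0, duration=length / 7.0 + 15.0,
                    stop_station=length, meta=meta)


def _build_car_following(lead_speed=12.5, lane_width=3.5, length=1600.0,
                         lead_start=250.0, v0=15.0, duration=90.0, **_):
    # the lead starts far enough ahead that the ego reaches its desired
    # speed before the risk field touches the lead: the approach then
    # happens at V_des for every lead speed
    road = RoadGeometry([Straight(length + 150.0)], lane_width)
    lead = Obstacle(lead_start, 0.0, lead_speed)
    meta = {"lead": 0}
    return Scenario("car_following", road, [_ego_band(lane_width)], [lead],
                    CostSchema(), ego_v0=v0, duration=duration,
                    stop_station=length, meta=meta)


def _build_overtaking(lead_speed=7.5, lane_width=3.5, ovt_width=3.5,
                      length=1100.0, lead_start=150.0, v0=18.0,
                      duration=60.0, **_):
    road = RoadGeometry([Straight(length + 150.0)], lane_width)
    bands = [
        LaneBand("overtake", lane_width / 2, lane_width / 2 + ovt_width),
        _ego_band(lane_width),
    ]
    lead = Obstacle(lead_start, 0.0, lead_speed)
    meta = {"lead": 0}
    return Scenario("overtaking", road, bands, [lead], CostSchema(),
                    ego_v0=v0, duration=duration, stop_station=length,
                    meta=meta)


def _build_oncoming(variant="both", lane_width=2.0, onc_width=2.0,
                    length=600.0, onc_speed=5.0, offset=0.3, v0=12.0,
                    duration=70.0, heading_err=math.radians(2.0), **_):
    road = RoadGeometry([Straight(length + 150.0)], lane_width)
    centre_lat = lane_width / 2 + onc_width / 2
    bands = [
        LaneBand("oncoming", lane_width / 2, lane_width / 2 + onc_width),
        _ego_band(lane_width),
    ]
    obstacles = []
    if variant in ("centre", "both"):
        obstacles.append(Obstacle(450.0, centre_lat, -onc_speed))
    if variant in ("offset", "both"):
        s0 = 620.0 if variant == "both" else 450.0
        obstacles.append(Obstacle(s0, centre_lat - offset, -onc_speed))
    if variant not in ("absent", "centre", "offset", "both"):
        raise ValueError(f"unknown oncoming variant {variant!r}")
    # steady window starts past the entry transient so encounter effects
    # are not masked by the entry dip
    meta = {"steady": {"s_lo": 250.0, "s_hi": length - 100.0},
            "variant": variant}
    # entered slightly angled toward the road centre, as when joining the
    # section from the rest of the track; the satisficing controller then
    # settles at an off-centre lateral position instead of the lane centre
    return Scenario("oncoming", road, bands, obstacles, CostSchema(),
                    ego_v0=v0, ego_heading_err=heading_err,
                    duration=duration, stop_station=length, meta=meta)


def _build_full_track(connector=100.0, **_):
    """All seven scenarios chained with connector straights."""
    parts = [
        _build_curve_radius(R=200.0),
        _build_lane_width(w=3.0),
        _build_obstacle(encroachment=0.9),
        _build_furniture(symmetric=False),
        _build_car_following(lead_speed=12.5, length=900.0, duration=60.0),
        _build_overtaking(lead_speed=7.5, length=800.0),
        _build_oncoming(variant="both"),
    ]
    segments = []
    bands = []
    obstacles = []
    offset = 0.0
    width = parts[0].road.lane_width
    for i, part in enumerate(parts):
        for band in part.bands:
            s_hi = band.s_hi if math.isfinite(band.s_hi) else part.road.length
            bands.append(replace(band, s_lo=band.s_lo + offset,
                                 s_hi=s_hi + offset))
        for obs in part.obstacles:
            obstacles.append(replace(obs, station0=obs.station0 + offset))
        segments.extend(part.road.segments)
        offset += part.road.length
        if i < len(parts) - 1:
            bands.append(_ego_band(width, offset, offset + connector))
            segments.append(Straight(connector))
            offset += connector
    road = RoadGeometry(segments, width)
    meta = {"parts": [p.name for p in parts]}
    return Scenario("full_track", road, bands, obstacles, CostSchema(),
                    ego_v0=18.0, duration=offset / 5.0, meta=meta)


_BUILDERS = {
    "curve_radius": _build_curve_radius,
    "lane_width": _build_lane_width,
    "obstacle": _build_obstacle,
    "furniture": _build_furniture,
    "car_following": _build_car_following,
    "overtaking": _build_overtaking,
    "oncoming": _build_oncoming,
    "full_track": _build_full_track,
}


def build_scenario(name: str, overrides: dict | None = None) -> Scenario:
    """Build one of the named study scenarios, with optional overrides."""
    if name not in _BUILDERS:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")
    sc = _BUILDERS[name](**(overrides or {}))
    sc.meta.setdefault("overrides", dict(overrides or {}))
    return sc
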