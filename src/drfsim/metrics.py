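"""Behavioural metrics computed from trajectory logs.

These summarize a run the way the driver-behaviour literature does:
curve cutting (TTR), swerving (SDLP), obstacle clearance and slow-down,
car-following headway and braking intensity, overtaking distance and
TTC at initiation.  All window/threshold conventions are keyword
arguments with declared defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from .kinematics import VehicleSpec
from .scene import Obstacle, Scenario
from .simulator import TrajectoryLog

__all__ = [
    "MetricsReport",
    "ttr",
    "sdlp",
    "thw_pref",
    "braking_intensity",
    "overtake_stats",
    "lateral_stats",
    "scenario_metrics",
    "write_report",
]


@dataclass
class MetricsReport:
    scenario: str
    values: dict = dfield(default_factory=dict)
    notes: dict = dfield(default_factory=dict)


def _segment(log: TrajectoryLog, s_lo: float, s_hi: float):
    df = log.df
    m = (df["station"] >= s_lo) & (df["station"] <= s_hi)
    if not m.any():
        raise ValueError(f"log does not cover stations [{s_lo}, {s_hi}]")
    return df[m]


def ttr(log: TrajectoryLog, curve: dict) -> float:
    """Trajectory transection rate at the curve midpoint.

    TTR = e_inside / (w/2): the lateral deviation toward the inside of
    the curve, normalized by the half lane width.  Positive values mean
    curve cutting.  This is a declared approximation of the literature
    metric (the original windows the whole curve); reports flag it.
    ``curve`` needs keys s_lo, s_hi, direction, lane_width.
    """
    if curve["s_hi"] <= curve["s_lo"]:
        raise ValueError("curve segment must have positive length")
    mid = 0.5 * (curve["s_lo"] + curve["s_hi"])
    df = log.df
    if df["station"].max() < mid or df["station"].min() > mid:
        raise ValueError("log does not cover the curve midpoint")
    e_mid = float(np.interp(mid, df["station"], df["e"]))
    inward = 1.0 if curve["direction"] == "left" else -1.0
    return inward * e_mid / (curve["lane_width"] / 2)


def sdlp(log: TrajectoryLog, s_lo: float, s_hi: float) -> float:
    """Standard deviation of lateral position over a steady segment.

    Population form (ddof=0), so a +-a alternation has SDLP exactly a.
    """
    seg = _segment(log, s_lo, s_hi)
    return float(np.std(seg["e"].to_numpy(), ddof=0))


def _gap_series(log: TrajectoryLog, lead: Obstacle, spec: VehicleSpec):
    df = log.df
    t = df["t"].to_numpy()
    gap = (lead.station_at(0) + lead.speed * t - lead.length / 2) \
        - (df["station"].to_numpy() + spec.length / 2)
    return t, gap, df["v"].to_numpy()


def thw_pref(log: TrajectoryLog, lead: Obstacle,
             spec: VehicleSpec = VehicleSpec(), steady_tol: float = 0.25,
             steady_min: float = 10.0) -> float | None:
    """Preferred time headway under steady-state car following.

    Bumper-to-bumper gap over ego speed, averaged over the longest
    window where |d(gap)/dt| stays below ``steady_tol`` m/s for at least
    ``steady_min`` seconds.  Returns None when no steady window exists.
    """
    t, gap, v = _gap_series(log, lead, spec)
    if len(t) < 3:
        return None
    rate = np.gradient(gap, t)
    ok = np.abs(rate) < steady_tol
    best = (0, 0)
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            if t[j] - t[i] > best[1] - best[0]:
                best = (t[i], t[j])
            i = j + 1
        else:
            i += 1
    if best[1] - best[0] < steady_min:
        return None
    m = (t >= best[0]) & (t <= best[1])
    return float(np.mean(gap[m] / np.maximum(v[m], 1e-9)))


def braking_intensity(log: TrajectoryLog, onset_threshold: float = -0.3,
                      window: float = 3.0) -> float | None:
    """Deceleration at the onset of braking.

    Onset is the first step with acceleration below ``onset_threshold``
    m/s^2; intensity is the mean acceleration over [onset, onset + window].
    The window spans the initial braking phase at the model's
    speed-control timescale (1/k_v ~ 7 s); sub-second windows alias the
    controller's case switching.  Returns None when the run contains no
    braking event.
    """
    df = log.df
    if len(df) < 3:
        return None
    t = df["t"].to_numpy()
    a = np.gradient(df["v"].to_numpy(), t)
    idx = np.flatnonzero(a < onset_threshold)
    if len(idx) == 0:
        return None
    t0 = t[idx[0]]
    m = (t >= t0) & (t <= t0 + window)
    return float(np.mean(a[m]))


def overtake_stats(log: TrajectoryLog, lead: Obstacle,
                   spec: VehicleSpec = VehicleSpec(),
                   lat_threshold: float = 0.25, clear_ahead: float = 5.0,
                   toward: float = 1.0):
    """Overtake distance and TTC at manoeuvre initiation.

    Start: first step where the lateral deviation has moved more than
    ``lat_threshold`` from its initial value toward the overtake lane
    (sign ``toward``).  End: ego rear bumper ``clear_ahead`` metres ahead
    of the lead front bumper.  Distance is the ego path length between
    them (trapezoidal integration of speed); TTC is the bumper gap over
    the closing speed at start.  Returns ``(distance, ttc)`` or None when
    no overtake occurred (including a lead faster than the ego).
    """
    df = log.df
    if len(df) < 3:
        return None
    t = df["t"].to_numpy()
    e = df["e"].to_numpy()
    v = df["v"].to_numpy()
    station = df["station"].to_numpy()
    baseline = e[0]
    dev = toward * (e - baseline)
    starts = np.flatnonzero(dev > lat_threshold)
    if len(starts) == 0:
        return None
    i0 = int(starts[0])
    gap = (lead.station_at(0) + lead.speed * t - lead.length / 2) \
        - (station + spec.length / 2)
    closing = v[i0] - lead.speed
    if closing <= 0:
        return None
    ahead = (station - spec.length / 2) \
        - (lead.station_at(0) + lead.speed * t + lead.length / 2)
    ends = np.flatnonzero(ahead[i0:] >= clear_ahead)
    if len(ends) == 0:
        return None
    i1 = i0 + int(ends[0])
    distance = float(np.trapezoid(v[i0:i1 + 1], t[i0:i1 + 1]))
    ttc = float(gap[i0] / closing)
    return distance, ttc


def lateral_stats(log: TrajectoryLog, s_lo: float | None = None,
                  s_hi: float | None = None,
                  obstacle_station: float | None = None) -> dict:
    """Lateral-deviation and speed summaries over a segment.

    Returns mean/min/max lateral deviation and min speed; when
    ``obstacle_station`` is given, also the deviation at that station.
    """
    df = log.df
    if s_lo is None:
        s_lo = float(df["station"].min())
    if s_hi is None:
        s_hi = float(df["station"].max())
    seg = _segment(log, s_lo, s_hi)
    e = seg["e"].to_numpy()
    out = {
        "mean_e": float(np.mean(e)),
        "min_e": float(np.min(e)),
        "max_e": float(np.max(e)),
        "min_v": float(np.min(seg["v"].to_numpy())),
        "mean_v": float(np.mean(seg["v"].to_numpy())),
    }
    if obstacle_station is not None:
        out["e_at_obstacle"] = float(
            np.interp(obstacle_station, df["station"], df["e"]))
        out["v_at_obstacle"] = float(
            np.interp(obstacle_station, df["station"], df["v"]))
    return out


def scenario_metrics(log: TrajectoryLog, scenario: Scenario,
                     spec: VehicleSpec = VehicleSpec()) -> MetricsReport:
    """Compute the metrics appropriate to a scenario's family."""
    rep = MetricsReport(scenario.name)
    meta = scenario.meta
    if "curve" in meta:
        rep.values["ttr"] = ttr(log, meta["curve"])
        rep.notes["ttr"] = "approximate TTR: midpoint deviation / half width"
        mid = 0.5 * (meta["curve"]["s_lo"] + meta["curve"]["s_hi"])
        rep.values["speed_at_curve_centre"] = float(
            np.interp(mid, log.df["station"], log.df["v"]))
    if "steady" in meta:
        st = meta["steady"]
        rep.values["sdlp"] = sdlp(log, st["s_lo"], st["s_hi"])
        rep.values.update(
            {f"steady_{k}": v for k, v in
             lateral_stats(log, st["s_lo"], st["s_hi"]).items()})
    if "obstacle_station" in meta:
        rep.values.update(lateral_stats(
            log, obstacle_station=meta["obstacle_station"]))
    if "row" in meta:
        row = meta["row"]
        rep.values.update(
            {f"row_{k}": v for k, v in
             lateral_stats(log, row["s_lo"], row["s_hi"]).items()})
    if "lead" in meta:
        lead = scenario.obstacles[meta["lead"]]
        rep.values["thw_pref"] = thw_pref(log, lead, spec)
        rep.values["braking_intensity"] = braking_intensity(log)
        ovt = overtake_stats(log, lead, spec)
        if ovt is not None:
            rep.values["overtake_distance"], rep.values["ttc_init"] = ovt
    return rep


def write_report(rep: MetricsReport, path) -> None:
    """Key-value structured-text metrics report."""
    with open(path, "w") as fh:
        fh.write("# drfsim-metrics v1\n")
        fh.write(f"scenario\t{rep.scenario}\n")
        for k, v in rep.values.items():
            fh.write(f"{k}\t{v}\n")
        for k, v in rep.notes.items():
            fh.write(f"# note {k}: {v}\n")
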