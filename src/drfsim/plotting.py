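"""Plotting helpers: risk-field surfaces and trajectory overviews."""

from __future__ import annotations

import numpy as np

from .field import DRFParams, FieldGrid, evaluate
from .kinematics import VehicleSpec, VehicleState
from .simulator import TrajectoryLog


def plot_field_surface(state: VehicleState, spec: VehicleSpec,
                       params: DRFParams, grid: FieldGrid, ax=None):
    """3-D surface of the risk field over the scene (field-shape figure)."""
    import matplotlib.pyplot as plt

    z = evaluate(state, spec, params, grid)
    X, Y = grid.cell_centers()
    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    ax.plot_surface(X, Y, z.values, cmap="viridis", linewidth=0)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_zlabel("z")
    return ax


def plot_trajectory(log: TrajectoryLog, ax=None):
    """Speed and lateral deviation vs. distance along the lane centre."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(2, 1, sharex=True)
    s = log.df["station"]
    ax[0].plot(s, log.df["v"])
    ax[0].set_ylabel("v (m/s)")
    ax[1].plot(s, log.df["e"])
    ax[1].set_ylabel("lateral deviation (m)")
    ax[1].set_xlabel("distance along lane centre (m)")
    return ax


def dump_grid(grid: FieldGrid, path) -> None:
    """Dense grid dump with a geometry header (debug/plotting exchange)."""
    with open(path, "w") as fh:
        fh.write("# drfsim-grid v1\n")
        fh.write(f"# origin: {grid.origin[0]!r} {grid.origin[1]!r}\n")
        fh.write(f"# delta: {grid.delta!r}\n")
        fh.write(f"# theta: {grid.theta!r}\n")
        fh.write(f"# nx ny: {grid.nx} {grid.ny}\n")
        np.savetxt(fh, grid.values if grid.values is not None
                   else np.zeros((grid.ny, grid.nx)))
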