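"""Recovering driver parameters from a recorded trajectory.

Direct estimation of the desired speed and acceleration gain from a
standing-start run, and a small grid search refitting the risk
threshold from a model-generated reference.
"""

import numpy as np

import drfsim as d

# direct estimation from an exact exponential speed rise
t = np.arange(0.0, 70.0, 0.05)
v = 21.6 * (1 - np.exp(-0.14 * t)) + 0.3 * np.exp(-0.14 * t)
station = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * 0.05)])
ref = d.ReferenceTrajectory(station, np.zeros_like(v), v, np.zeros_like(v))
est = d.direct_estimates(ref)
print(f"direct estimates: V_des = {est.v_des:.2f} m/s (truth 21.6), "
      f"k_v = {est.k_v:.3f} 1/s (truth 0.14)")

# grid-search refit of the risk threshold from a noiseless reference
scenario = d.build_scenario("obstacle", {"encroachment": 0.9,
                                         "length": 260.0,
                                         "obs_station": 160.0})
cfg = d.SimConfig(duration=16.0)
reference = d.synthesize_reference(d.DRF_DEFAULT, d.get_preset("normal"),
                                   scenario, sigma=(0, 0, 0), seed=0, cfg=cfg)
space = d.SearchSpace({"c_t": np.array([2400.0, 3200.0, 4000.0])},
                      stages=2, refine_factor=5)
fit = d.grid_search(space, reference, scenario, cfg=cfg)
print(f"grid search: C_t = {fit.params['c_t']:.0f} (truth 3000), "
      f"objective {fit.objective:.4f}")
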