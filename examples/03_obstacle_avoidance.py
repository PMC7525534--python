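"""Steering and braking around a parked car.

A sedan encroaches 0.9 or 1.4 m into a 3.5-m lane.  The model steers
away from it and slows down, more for the wider encroachment.
"""

import drfsim as d

for enc in (0.9, 1.4):
    scenario = d.build_scenario("obstacle", {"encroachment": enc})
    log = d.run(scenario, d.DRF_DEFAULT, d.get_preset("normal"),
                d.SimConfig(), d.EGO_SPEC)
    stats = d.lateral_stats(log, obstacle_station=250.0)
    print(f"encroachment {enc:.1f} m: lateral deviation at the obstacle "
          f"{stats['e_at_obstacle']:+.3f} m, speed there "
          f"{stats['v_at_obstacle']:5.2f} m/s")

print()
print("Negative deviation = away from the left-side obstacle; both the")
print("deviation and the slow-down grow with the encroachment.")
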