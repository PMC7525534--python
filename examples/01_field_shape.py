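"""Shape of the driver's risk field under speed and steering.

Evaluates the field on a grid for a few vehicle states and prints its
peak height and total mass.  The field is a torus with a Gaussian
cross-section bent along the predicted path: it lengthens with speed
(fixed preview time) and widens with |steering|, asymmetrically
(outer side wider), which is what later produces corner cutting.
"""

import numpy as np

import drfsim as d

grid = d.FieldGrid(origin=(-5.0, -20.0), delta=0.25, nx=480, ny=160)

for v, delta in [(10.0, 0.0), (20.0, 0.0), (20.0, 0.05), (20.0, -0.05)]:
    state = d.VehicleState(0.0, 0.0, 0.0, v, delta)
    field = d.evaluate(state, d.EGO_SPEC, d.DRF_DEFAULT, grid)
    mass = field.values.sum() * grid.delta**2
    print(f"v={v:5.1f} m/s  delta={delta:+.2f} rad  "
          f"peak={field.values.max():6.2f}  mass={mass:8.2f} m^2")

print()
print("The peak sits at the car and equals p*(v*t_la)^2; the mass grows")
print("with speed (longer field) and with |steering| (wider field) --")
print("the signal-dependent-noise idea: bigger commands, more spread.")
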