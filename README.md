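# drfsim — a perceived-risk driver model in a 2D simulator

Human drivers handle curves, obstacles, car following, overtaking and
oncoming traffic without switching between specialized control laws.
`drfsim` implements a driver model in which all of these behaviours
emerge from a single principle: keep *perceived risk* below an
individual threshold while pursuing a desired speed.

Perceived risk is quantified as the product of two ingredients, summed
over the driving scene:

* the **driver's risk field** `z(x, y)` — the driver's subjective
  probability of occupying a position within the next `t_la` seconds: a
  torus with Gaussian cross-section bent along the predicted path of
  the kinematic bicycle model (`R = L/tan δ`), with height
  `a(s) = p (s − v t_la)²` and width `σ_i(s) = (m + k_i|δ|) s + c`
  growing with the steering magnitude (signal-dependent noise);
* a **cost map** of the scene: 0 on the ego lane, 3.5 on an overtake
  lane, 14 on an oncoming lane, 500 off-road, 2500 under car footprints.

A satisficing threshold controller turns the scalar risk
`C = Σ z·cost·Δ²` into steering and speed commands: below the threshold
`C_t` it simply tracks the desired speed and the road heading; above
it, it applies the *minimal* steering correction that restores
acceptability, or brakes in proportion to the unavoidable excess.  The
model therefore does not track the lane centre — any low-risk state is
acceptable — which is exactly what produces its human-like lateral
behaviour.

The package is used from Python: scenario builders for the seven study
scenarios (curve radius, lane width, on-road obstacle, roadside
furniture, car following, overtaking, oncoming traffic), a
deterministic closed-loop simulator, behavioural metrics (curve-cutting
TTR, SDLP, time headway, braking intensity, overtake distance, TTC),
and grid-search parameter estimation with a synthetic-reference
generator.  A thin `drfsim` command-line tool wraps running, metrics,
sweeps, fitting and plotting.

## A worked example

```python
import drfsim as d

scenario = d.build_scenario("oncoming", {"variant": "absent"})
log = d.run(scenario, d.DRF_DEFAULT, d.get_preset("normal"),
            d.SimConfig(), d.EGO_SPEC)
df = log.df
steady = df[(df.station >= 200) & (df.station <= 500)]
print(f"mean speed    {steady.v.mean():.2f} m/s")
print(f"lateral bias  {steady.e.mean():+.3f} m toward the road centre")
```

prints

```
mean speed    19.95 m/s
lateral bias  +0.450 m toward the road centre
```

On a narrow two-lane rural road (2-m ego lane, 2-m oncoming lane, no
barrier) with no traffic, the model does not drive on its lane centre:
the paved but empty oncoming lane on the left is far less dangerous
than the road boundary on the right, so the satisficing controller
settles about half a metre toward the road centre — and slows from its
desired 21.6 m/s to what the narrow road permits at its risk threshold.

The `examples/` directory holds one short script per capability (field
shape, empty-road speed control, obstacle avoidance, car following,
oncoming traffic, parameter fitting); each prints the numbers it
computes and what they mean.  Or from the shell:

```
drfsim run --scenario obstacle -O encroachment=1.4 --out run.tsv
drfsim metrics --log run.tsv
drfsim sweep --family curve_radius --preset sport
```

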