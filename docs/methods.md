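# Methods

## The model

`drfsim` implements a perceived-risk driver model built from two parts.

**The driver's risk field (DRF).** The driver's belief about where the
car might be within the next `t_la` seconds is a two-dimensional field
`z(x, y)` bent along the *predicted path* — the constant-control arc of
the kinematic bicycle model, radius `R = L / tan(|δ|)` (wheelbase `L`,
steering angle `δ`), truncated at the look-ahead distance `v·t_la`.
At arc length `s` along the path and offset `d` from it,

    z = a(s) · exp(−d² / (2 σ_i(s)²)),
    a(s)   = p (s − v t_la)²            for s ∈ [0, v t_la], else 0,
    σ_i(s) = (m + k_i |δ|) s + c,       i = inner (toward the turn
                                        centre, k₁) or outer (k₂).

The height parabola is largest at the car and vanishes at the preview
horizon; the width grows linearly with distance and with the magnitude
of the steering command, mirroring signal-dependent noise in human
motor control.  With `k₁ < k₂` the field is asymmetric: the inner side
stays narrow, which makes cutting the inside of a curve cheap and is
the origin of the model's corner-cutting.

**The satisficing controller.**  The driving scene is rasterized into a
cost map (ego lane 0, overtake lane 3.5, oncoming lane 14 = 4× the
overtake lane, off-road 500, car footprints 2500).  The perceived risk
is the field–cost product summed over the grid,

    C = Σ_cells z · cost · Δ²,

with cell area `Δ²` included so that `C` approximates the continuous
integral `∬ z·cost dA` and is independent of the grid resolution; the
thresholds below are calibrated on that scale.  The controller compares
`C` with an individual threshold `C_t` and the speed `v` with a desired
speed `V_des`, giving four cases:

1. `C < C_t, v ≤ V_des` — accelerate at rate `k_v (V_des − v)`, steer
   with the heading controller (below).
2. `C > C_t, v ≤ V_des` — search the steering angle `δ_op` minimizing
   `C(δ)` at the current speed.
   * 2a: if `C(δ_op) < C_t`, apply only the *minimal* correction
     `δ_opt` that brings `C` down to `C_t` (the root of `C(δ) = C_t`
     nearest the current steering) and keep accelerating.  The model
     satisfices: it never over-corrects toward the risk minimum.
   * 2b: otherwise brake at rate `k_vc (C(δ_op) − C)` and steer from
     the heading baseline a small bounded fraction toward `δ_op`
     (see *Controller anchoring* below).
3. `C < C_t, v > V_des` — decelerate toward `V_des`, heading steering.
4. `C > C_t, v > V_des` — brake at rate `k_vc (C_t − C) + k_v (V_des −
   v)`, steering as in 2b.

The heading controller nudges the steering toward alignment with the
road, `δ ← δ + dt·k_h·(φ_road − φ_car)`, with both headings evaluated
`t_lah` seconds ahead along the predicted path.

All printed gains are treated as continuous-time rates and multiplied
by the integration step, so behaviour is step-size invariant (a
`literal_step_updates` switch reproduces the raw per-step form).

### Controller anchoring (cases 2b/4)

A naive reading of case 2b applies `δ_op` outright every step.  In
closed loop this is unstable in a subtle way: once the steering tracks
the per-step optimum, the relief term `C(δ_op) − C` collapses to ~0, so
the braking law never brakes, while the accumulated marginal sidesteps
slowly carry the car around obstacles it should brake for — in the
car-following scenario the ego ends up squeezing past the lead car
through the shoulder at enormous risk with zero deceleration.  Anchoring
the steering at the heading controller keeps the relief measured from a
road-aligned baseline (it then tracks the rate at which the obstacle
encroaches on the field) and restores braking, but suppresses the
lateral yielding the model should show to oncoming traffic.  The
implementation therefore steers

    δ = δ_head + α (δ_op − δ_head),   α = 0.05 (SimConfig.avoidance_blend)

which preserves the braking signal (car following settles at a steady
headway of ≈2.8–3.0 s with braking intensities of 1.6–2.0 m s⁻²) while
still yielding laterally to threats that steering genuinely mitigates
(the oncoming-traffic encounters).  α is the one structural constant
the model adds; behaviour is insensitive to it between ~0.03 and ~0.08,
and the two failure modes above reappear at α → 1 and α → 0.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| p | height-parabola steepness | 0.0064 | — |
| t_la | preview (look-ahead) time | 3.5 | s |
| m | width slope at zero steering | 0.001 | — |
| c | half-width at the car (car width / 4) | 0.5 | m |
| k₁, k₂ | inner/outer width gain per rad | 0, 1.3823 | rad⁻¹ |
| C_t | risk threshold (normal / sport) | 3000 / 5200 | risk |
| V_des | desired speed (normal / sport) | 21.6 / 26.0 | m s⁻¹ |
| k_v | speed-tracking rate (normal / sport) | 0.14 / 0.30 | s⁻¹ |
| k_vc | risk-to-deceleration rate | 1.5·10⁻⁴ | (risk·s)⁻¹ m s⁻¹ |
| k_h | heading-controller rate | 1.0 | s⁻¹ |
| t_lah | heading preview time | 1.0 | s |

`k_h` and `t_lah` are free constants of the heading controller; they are
not part of the fitted parameter set.  A heading preview as long as the
field preview (3.5 s) makes the controller steer toward the road
direction ~70 m ahead and cut curves so hard the car leaves the lane;
1.0 s tracks curves stably while leaving room for the field asymmetry
to produce realistic corner cutting (TTR ≈ 0.6 at R = 100 m falling to
≈ 0.18 at R = 400 m).

Angle arguments are radians everywhere in the API; the CLI accepts an
explicit `deg` suffix.  Steering is treated as straight below 10⁻⁶ rad
(the arc deviates from the ray by under a millimetre across the whole
preview there), and commanded steering is clamped to ±45°; candidate
angles beyond the steering lock (|δ| ≥ π/2), where the bicycle model's
tangent changes sign, evaluate to infinite risk.

## Numerics

* Integration: forward Euler at dt = 0.05 s (configurable).  The
  closed-loop dt-sensitivity on the empty road is below 2% when dt is
  halved.
* Field/cost grid: a moving window aligned with the vehicle, 0.25-m
  cells, extending 2 m back, `1.2·v·t_la + 10` m forward and ±15 m
  laterally.  The risk sum skips zero-cost cells and >6σ tails and is
  JIT-compiled when numba is available (a numpy reference
  implementation is pinned against it in the tests).  Field mass that a
  candidate steering angle would push outside the window is charged the
  off-road cost via a 1-m line quadrature along the predicted path, so
  the optimizer cannot mistake window clipping for safety.
* Steering search: deterministic coarse sweep (0.1 rad) over the
  admissible range, a fine sweep at the full search
  resolution (1 mrad, ±40 mrad) around the current steering — the
  useful minima are milliradian-scale basins hugging the current
  steering that bracket-based local search alone misses — and
  golden-section refinement.
  The satisficing root `δ_opt` is found by marching from the current
  steering toward `δ_op` and bisecting the first threshold crossing.
* Grid-search fitting: exhaustive evaluation in lexicographic order
  (first-wins tie-break), two coarse-to-fine stages with refinement
  factor 5, candidates that fail to simulate scored +∞.  The objective
  is the unweighted sum of squared differences of steering, speed and
  lateral deviation on a 1-m station grid.

## Scenarios and their entry conditions

The seven study scenarios (curve radii, lane widths, on-road obstacle,
roadside furniture, car following, overtaking, oncoming traffic) are
generated by `build_scenario`, each with the published geometry: curve
radii 100–400 m, lane widths 2.5–4.0 m, a sedan encroaching 0.9 or
1.4 m on a 3.5-m lane, a 200-m row of 10 cars outside the boundary,
leads at 12.5/15 m s⁻¹, overtaken cars at 7.5/10 m s⁻¹ with a 3.5-m
overtake lane, and 5 m s⁻¹ oncoming cars on a 2-m oncoming lane (the
second offset 0.3 m toward the ego car).  Straight scenarios carry a
150-m paved run-out beyond the measurement stop so end-of-road risk
never contaminates the metrics, and a full-track builder chains all
seven with 100-m connectors.

Entry conditions matter because the controller satisfices: lateral
position freezes wherever the transient leaves it.  The lane-width and
oncoming builders therefore start the car angled 2° off the road
direction, as when joining the section from the rest of a track; on the
oncoming road this entry lets the model settle at its characteristic
≈0.45-m bias toward the road centre (the result is insensitive to the
angle between 1° and 4°).  The car-following builder starts the lead
250 m ahead so the approach always begins from the desired speed.

## Synthetic references

`synthesize_reference` stands in for human driving data: it runs the
model, resamples steering/speed/lateral deviation onto a 1-m station
grid and adds independent seeded Gaussian noise per signal.  It
reproduces what parameter-recovery tests need — a distance-indexed
reference with controllable noise — but none of the structure of real
human data (trial-to-trial correlation, drift, perceptual delays), so
recovery results demonstrate identifiability of the model's parameters,
not fidelity to human estimation problems.

## Known limitations

* **Roadside furniture is sub-threshold.**  With the published widths
  (σ ≤ 0.58 m while driving straight) a car row centred 2.75 m off the
  lane centre lies more than 3σ from the path: the symmetric case peaks
  at C ≈ 820 against a threshold of 3000, so the model does not react
  to roadside furniture at all.  The corresponding trend tests are left
  failing rather than inflating the field or the costs.
* **SDLP does not grow with lane width.**  The deterministic model
  trades speed for lateral margin, so its excursions are nearly
  width-independent and steady-state swerving is essentially zero; the
  lane-width *speed* trend is reproduced strictly.  Human SDLP growth
  presumably needs ongoing perception/action noise, which the model
  deliberately lacks.
* The model never returns to its lane after overtaking (satisficing:
  the overtake lane is cheap), cannot perform accelerative overtakes
  (speed capped at `V_des`), has no anticipation of other cars' motion
  (cost maps use current positions), and no tactical knowledge
  (intersections, traffic rules).  The first of these is asserted by a
  test as behaviour fidelity, not patched away.
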