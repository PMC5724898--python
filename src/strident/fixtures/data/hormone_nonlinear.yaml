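name: hormone_nonlinear
description: >
  Nonlinear circuit of hormonal reactions: a regulated variable x is
  produced at a basal rate b0 (plus an external input u) and removed
  bilinearly by a hormone y with gain s; the hormone is secreted by a gland
  of functional mass z with gain p and cleared at rate g; the gland mass
  grows or shrinks multiplicatively according to the deviation of x from
  its set point.  The slow gland-mass integral feedback pins the steady
  state of x, producing exact adaptation, and the two free scalings of the
  unmeasured pair (y, z) compensate changes in s and p, producing dynamical
  compensation of the x output with respect to both gains.
provenance: >
  Reconstruction (synthetic): the published figure shows the circuit
  topology (hormone-mediated removal, gland-mass feedback, gains p and s)
  but not the full right-hand sides, which are only in a supplementary code
  archive.  The equations here mirror the glucose circuit's structure at
  the level the topology fixes and reproduce the documented analysis
  outcomes (exact adaptation, dynamical compensation, {p, s} structurally
  unidentifiable from x).
states: [x, y, z]
params: [p, s]
inputs: [u]
constants:
  b0: 1
  g: 1
  m: 1/10
  x_ref: 1
dynamics:
  x: "b0 + u - s*y*x"
  y: "p*z*x - g*y"
  z: "m*z*(x - x_ref)"
observables:
  x: x
  y: y
  z: z
constraints:
  - x > 0
  - y > 0
  - z > 0
defaults:
  p: 1
  s: 1
initial_map:
  kind: steady_state
  guess: {x: 1.0, y: 1.0, z: 1.0}
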