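name: linear_PI
description: >
  Linear circuit with proportional-integral feedback and one additional
  state: the error y - y_ref is integrated by z (fed back with gain s) and
  low-pass filtered into w with a fixed time constant tau (fed back with
  gain p).  Integral action gives exact adaptation of y; the transient
  depends on both gains, so there is no dynamical compensation and both
  gains are structurally identifiable from y under a generic input.
provenance: >
  Reconstruction (synthetic): the published figure shows a linear
  proportional-integral circuit with an additional state variable and gain
  constants p and s, but the full right-hand sides are only in a
  supplementary code archive.  The filtered proportional branch with a
  fixed, known time constant realizes the described topology while keeping
  both gains identifiable, matching the documented verdict.
states: [y, z, w]
params: [p, s]
inputs: [u]
constants:
  y_ref: 1
  tau: 10
dynamics:
  y: "u - s*z - p*w"
  z: "y - y_ref"
  w: "(y - y_ref - w)/tau"
observables:
  y: y
defaults:
  p: 1
  s: 1
initial_map:
  kind: steady_state
  guess: {y: 1.0, z: 0.0, w: 0.0}
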