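name: linear_integral
description: >
  Linear circuit with integral feedback on the regulated output y: the
  error y - y_ref is integrated by z and fed back with gain s, and a direct
  feedback branch acts on the error with gain p.  Integral action pins the
  steady state of y at y_ref for every (p, s), so the circuit shows exact
  adaptation; the transient response depends on both gains, so it has no
  dynamical compensation and both gains are structurally identifiable from
  y under a generic input.
provenance: >
  Reconstruction (synthetic): the published figure shows a linear
  integral-feedback circuit with feedback gain constants p and s but not
  the full right-hand sides (supplementary code archive only).  The form
  here realizes that topology; note that a variant in which the unmeasured
  integrator couples only through the two unknown gains would make {p, s}
  jointly unidentifiable (a scaling symmetry), contradicting the documented
  verdict, so the direct branch must act on the measured error.
states: [y, z]
params: [p, s]
inputs: [u]
constants:
  y_ref: 1
dynamics:
  y: "u - p*(y - y_ref) - s*z"
  z: "y - y_ref"
observables:
  y: y
defaults:
  p: 1
  s: 1
initial_map:
  kind: steady_state
  guess: {y: 1.0, z: 0.0}
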