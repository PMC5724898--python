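name: toy_LTI
description: >
  Small linear time-invariant system with no unknown parameters, used to
  cross-check the Lie-derivative observability matrix against the Kalman
  observability matrix [C; CA; ...].
provenance: Defined for testing.
states: [x1, x2]
params: []
inputs: [v]
dynamics:
  x1: "-x1 + 2*x2 + v"
  x2: "x1 - 3*x2"
observables:
  y: x1
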