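name: toy_product
description: >
  One-state toy with a product of two rate parameters: dw/dt =
  -p1*p2*w + v, y = w.  Only the product p1*p2 enters the input-output
  behaviour, so each factor alone is structurally unidentifiable -- the
  minimal example of a symmetric parameter combination.
provenance: Defined for testing; the canonical p1 x p2 symmetry example.
states: [w]
params: [p1, p2]
inputs: [v]
dynamics:
  w: "-p1*p2*w + v"
observables:
  w: w
defaults:
  p1: 1
  p2: 2
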