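name: betaIG
description: >
  Minimal glucose homeostasis circuit with three states: beta-cell
  functional mass (beta, mg), plasma insulin (I, uU/ml) and plasma glucose
  (G, mM).  Glucose is produced at a constant hepatic rate u0 and by meal
  inputs u(t), and removed at an insulin-independent rate c plus an
  insulin-dependent rate si*I (si is the insulin sensitivity).  Insulin is
  secreted by beta cells with gain p and a sigmoidal dependence on glucose
  with half-point alpha, and cleared at rate gamma.  Beta-cell mass turns
  over slowly, with antagonistic glucose-dependent proliferation and
  removal rates whose crossing point sets the glucose baseline; the
  real-exponent term (8.4/G)^1.7 makes the system non-rational.  Time is in
  minutes, so the slow beta-cell compensation plays out over weeks to
  months of model time.
provenance: >
  Topology, state/parameter roles, the non-rational rate term (8.4/G)^1.7
  and the reference values si = 5e-4, p = 0.03 follow the published
  glucose-homeostasis circuit; the remaining rate constants are the
  standard minutes-scale values of the Topp-lineage minimal model this
  circuit derives from (basal production 1/30 mM/min, insulin-independent
  clearance 1e-3 /min, insulin clearance 0.3 /min, beta-cell
  proliferation/removal maxima 0.021 and 0.025 per day with half-points
  8.4 and 4.8 mM and exponents 1.7 and 8.5).
states: [G, I, beta]
params: [alpha, gamma, c, p, si]
inputs: [u]
constants:
  u0: 1/30
  mu_plus: 14583/1000000000
  mu_minus: 17361/1000000000
dynamics:
  G: "u0 + u - (c + si*I)*G"
  I: "p*beta*G^2/(alpha^2 + G^2) - gamma*I"
  beta: "beta*(mu_plus/(1 + (8.4/G)^1.7) - mu_minus/(1 + (G/4.8)^8.5))"
observables:
  G: G
  I: I
  beta: beta
constraints:
  - G > 0
  - I >= 0
  - beta > 0
defaults:
  alpha: 8.4
  gamma: 0.3
  c: 0.001
  p: 0.03
  si: 0.0005
initial_map:
  kind: steady_state
  guess: {G: 5.1, I: 11.0, beta: 400.0}
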