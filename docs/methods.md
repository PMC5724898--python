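# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `strident`. It is the package's own account of its
science; every number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Model class and declarative format

Models are nonlinear time-invariant state-space systems
`dx/dt = f(x, p, u(t))`, `y = h(x, p)`, with constant parameters and known
inputs. Outputs never reference inputs directly. Models are declared in a
YAML document with sections for states, parameters, inputs, named
constants, dynamics, observables, domain constraints, default parameter
values and an optional steady-state initial map; expressions use infix
math with `^` for powers. Decimal literals are parsed into exact rationals
(`1.7 -> 17/10`) so that rational models stay exactly rational all the way
into the rank computation. Non-rational right-hand sides (real exponents,
exponentials) are first class; strict-positivity constraints (`G > 0`)
must be declared for the bases so differentiation and evaluation are well
defined. Serialization back to the same format round-trips symbolically
(property-tested on the whole catalog).

The steady-state initial map ξ(p) is realized numerically: a model may
store a guess, and `find_steady_state` solves `f(x, p, 0) = 0` (Powell
hybrid), accepting a root only if the residual max-norm is below 1e-10 and
no strictly-positive state has collapsed below 1e-9 (which would indicate a
degenerate boundary equilibrium such as zero regulator mass). Retries use
multiplicative multi-start over ±1.5 decades around the guess, because the
admissible equilibrium moves across decades when gain parameters change.
Identifiability analyses deliberately do **not** impose ξ(p): they treat
the initial state as generic, which is the natural setting for the rank
test; the steady-state map is used only by the simulation experiments,
whose definitions require it.

## Identifiability engine

**Augmentation.** A configuration fixes measured outputs and unknown
parameters; known parameters are substituted numerically (so only the
unknown subset enters the question), and unknown parameters join the state
with zero dynamics, giving `x̃` of dimension `n + q'`.

**Extended Lie derivatives.** `L_f h = (∂h/∂x̃)·f̃ + Σ_j (∂h/∂u⁽ʲ⁾)·u⁽ʲ⁺¹⁾`,
applied recursively. In the default *generic input* mode the input
derivatives `u, u', u'', …` are retained as free nonzero symbols up to the
current level — the identifiability question quantifies over arbitrary,
sufficiently exciting inputs. A *constant input* mode (all input
derivatives zero) is available for comparison.

**Matrix construction and stopping.** The observability–identifiability
matrix stacks the Jacobians `∂(L_f^i h)/∂x̃` for `i = 0 … L−1`. Under the
default rank-plateau rule, levels are added until the evaluated rank fails
to increase once, capped at the theoretical sufficient depth of `n + q'`
levels; for the codistribution spanned by the output differentials a
stalled filtration is stationary, so at a generic point the plateau rank
is the final rank. A fixed-depth mode exists for oracle comparisons.

**Backends.** Symbolic Lie derivatives of non-trivial vector fields grow
roughly geometrically with level (for the glucose circuit ~7x ops per
level), so the builder constructs Jacobian blocks symbolically only while
the running derivative stays below `symbolic_ops_limit` (default 300
sympy ops). Beyond that it continues numerically: the i-th extended Lie
derivative equals `i!` times the i-th Taylor coefficient of the output
along the flow when the input is the polynomial `Σ u⁽ʲ⁾ tʲ/j!`, so matrix
entries at a specialization point are obtained by truncated Taylor-series
(jet) propagation through `f`, with complex-step directional perturbation
of each augmented-state coordinate (step `10^(-dps/2)`; no subtractive
cancellation). The two backends agree to ~1e-40 on the bundled models
(unit-tested) and the switch point does not affect verdicts.

**Rank by randomized specialization.** All free symbols (augmented state,
input-derivative chain) are replaced by random positive rationals with
numerator and denominator drawn from [5, 40] (values roughly in
[1/8, 8]), redrawing if a domain constraint is violated; the rank at a
random point equals the generic rank except on a measure-zero set, so the
maximum over 3 independent draws (seed 0 by default; every report is
seed-deterministic) is reported. Rational specialized matrices are ranked
exactly over Q; otherwise a singular value decomposition at 50 decimal
digits is used with tolerance `max_dim · σ_max · 10^-(dps-12)`. If draws
disagree, the policy escalates once (3x draws, 2x digits) and reports the
larger rank with a flag — a spurious "unidentifiable" is the costlier
error. All verdicts are **local**.

**Classification.** With the plateaued matrix cached at its evaluation
points, each column is deleted in turn: unchanged rank marks that
parameter structurally unidentifiable (that state unobservable). When
several deficiencies overlap, the number of rank-preserving deletions can
exceed the rank deficit; the per-symbol map is the primary result and the
deficit `n + q' − rank` is a lower bound on it.

**Sweep.** The configuration sweep runs the classifier over the cross
product of output subsets and unknown-parameter scenarios (outputs outer,
scenarios inner), records per-cell failures in place, and renders a table
with rows = measured outputs, columns = unknown scenarios, cells = the
unidentifiable set (`-` when empty). For the glucose circuit this is
7 subsets x 4 scenarios = 28 configurations, completing in ~30 s.

## Simulation experiments

**Integration.** Trajectories use LSODA with rtol 1e-10 / atol 1e-12,
restarted at parameter-switch events and pulse edges with continuous
state; positivity constraints are checked on the result. Input signals
are sums of non-overlapping pulses over a zero baseline with strictly
positive onsets (`u(0) = 0` is required by the compensation definitions).
The default pulse is a C-infinity bump normalized so each pulse carries
area amplitude x width; square pulses are available and handled by
piecewise integration.

**Units and the meal scenario.** The glucose fixture uses minutes, mM
(glucose), uU/ml (insulin) and mg (β-cell mass). The meal train defaults
to 3 pulses of width 30 min spaced 360 min ("roughly six hours"), area
15 mM of glucose appearance per meal — the pulse amplitude/width are not
constrained by the circuit definition, and a property test confirms the
compensation verdicts are insensitive to the schedule, as they must be
for a property that quantifies over all inputs.

**Exact adaptation.** From the steady state under `k₁`, the parameter is
switched to `k₂` and integrated with zero input over a default horizon of
2e5 min; because the slow β-cell mode settles over months of model time,
the horizon is doubled (up to 3 times) until `‖f‖∞ < 1e-8` at the
endpoint, and the settled flag is reported. The adapted criterion is a
relative output deviation below 1e-3. For the glucose circuit, halving
the insulin sensitivity returns glucose to baseline within ~4e-9 while
insulin and β-cell mass settle at 2.000000x their pre-switch values.

**Output invariance.** Each parameter value is started from *its own*
adapted steady state and driven by the same input on a shared grid; the
verdict requires every tested signal (at least two structurally distinct
ones) to keep the maximum relative output deviation below 1e-6. The
underlying symmetry is exact, so the tolerance only absorbs integrator
error; the measured deviation for the glucose/sensitivity pair is ~1e-10,
four orders below the threshold, while non-compensated pairs fail by five
orders of magnitude (deviations ~0.1-0.2). Verdicts are reported per
(output, parameter) pair, never per model.

**Scaling symmetries.** The glucose circuit admits two exact compensation
symmetries: `{si -> si/k, I -> k·I, p -> k·p}` preserves glucose and
β-cell mass (parameter–parameter compensation), and
`{si -> si/k, I -> k·I, β -> k·β}` with `p` fixed preserves glucose alone
(parameter–state compensation) — the latter shows that the sensitivity
cannot be inferred from glucose even off steady state and with the gain
known, because coordinated changes of the two unmeasured states absorb
it. The experiment driver simulates both members of a pair (optionally
with a mid-run sensitivity switch at t = 1e5 over a 2e5-min window) and
reports per-state deviations raw and after undoing the expected scaling.

## Design choices made where the design was open

- **Generic initial state for rank tests, steady state for simulations**
  (see above): the two analyses answer different questions and the rank
  test must not be restricted to the adapted manifold.
- **Generic input mode as default**: the compensation definitions
  quantify over any time-dependent input, so identifiability claims are
  made for a sufficiently exciting input. Constant-input mode can only
  lower the rank.
- **Positive-only specialization values**: biological fixtures declare
  positivity; the positive orthant is open, so genericity is unaffected.
- **Known parameters substituted numerically before analysis** rather
  than carried symbolically: matches the scenario semantics (a known
  parameter is a number) and shrinks the expressions.
- **Fixture reconstruction**: the two linear circuits and the hormonal
  circuit ship as reconstructions from their documented topology; their
  files say so. A short null-space argument (recorded in the
  linear_integral file) shows any 2-state linear variant whose unmeasured
  integrator couples only through the two unknown gains would make the
  gain pair jointly unidentifiable, so the direct feedback branch must
  act on the measured error for the documented verdict to hold.

## What the synthetic experiments do and do not show

The simulation scenarios emulate the canonical study conditions: meal-like
pulse trains, a sensitivity switch with slow re-adaptation, and paired
trajectories under the compensation symmetries. They use the fixture's
literature-derived rate constants, noise-free measurements and exact
parameter switches. Passing them shows the engines are correct on models
whose ground truth is known analytically (symmetries, closed-form steady
states, Kalman-rank agreement on linear systems); it does not validate
the physiological realism of any fixture, address noisy-data (practical)
identifiability, or certify global — as opposed to local — properties.

## Known limitations

- Verdicts are local; global identifiability and identifiable parameter
  *combinations* are out of scope.
- Randomized rank is correct with overwhelming, not certain,
  probability; pathological models could in principle defeat a finite
  set of draws (mitigated by the escalation policy and seed
  determinism).
- The rank-plateau stop is generically sound but shares the usual caveat
  of numeric genericity; fixed-depth construction is available when the
  theoretical depth is wanted unconditionally.
- Time-varying parameters, PDE/DDE/stochastic/hybrid models and model
  decomposition are unsupported.
- The problem sizes used by the shipped experiments (3 rank draws,
  28-cell sweep, 2e5-min horizons with up to 3 doublings, 1500-2000-point
  grids) were chosen as the smallest that leave orders-of-magnitude
  margins between passing and failing outcomes.
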