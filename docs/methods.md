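# Methods

## Model semantics

A model is the declarative structure of an SBML Level 3 core-subset
document: compartments, species, parameters, reactions (with optional local
parameters, modifiers, and variable stoichiometries), assignment and rate
rules, initial assignments, and events without delay. Identifiers are
case-sensitive and live in one flat namespace across all component kinds,
matching SBML `SId` semantics.

Internal state is the vector of floating-species *amounts* (document
order), followed by the values of rate-rule parameter targets. Kinetic
laws, rules and triggers see species as *concentrations*
(amount / compartment size); compartment sizes are constant. Rate rules on
species are interpreted in concentration units and scaled by the
compartment size to yield amount derivatives. Booleans and numbers coerce
both ways (true = 1.0; a number is true iff nonzero), which is how MathML
that mixes the two maps onto one expression type.

Distribution draws (`normal`, `uniform`, `lognormal`, `exponential`,
`gamma`, `poisson`, `binomial`) are legal only in initial assignments and
event assignments, where they are resolved once per evaluation against the
model's seeded generator. Draws inside kinetic laws or rules are rejected:
a rate that re-randomises on every integrator stage has no consistent ODE
semantics, and stochastic dynamics are the SSA's job. Unsupported SBML
constructs (delays, algebraic rules, function definitions, constraints,
hierarchical composition) raise explicit errors naming the construct —
never a silent skip.

## Compilation

"Compilation" means generating Python source once per model — a single
kernel computing all reaction rates and rule derivatives, with assignment
rules inlined in topological order (a cycle is an error) — and executing
it into a callable. Inner loops never walk expression trees. Artifacts are
cached in memory by a content hash of the model structure, so loading the
same structure again, or restoring a snapshot, skips code generation
entirely; editing the model marks the compiled object stale, and evaluating
a stale model is an error rather than a silent inconsistency. Derivative
kernels (`∂v/∂x`, `∂v/∂p`, rule derivatives) are generated on demand by
symbolic differentiation (through sympy) and cached per (model,
symbol-tuple).

## Integrators

* **rk45** (default): embedded Dormand–Prince 5(4) pair. The error
  estimate is the weighted RMS of the 5th/4th-order difference with scale
  `abs_tol + rel_tol * max(|y0|, |y1|)`; accepted iff ≤ 1. Step-size
  controller: factor `0.9 * err^(-1/5)` clamped to [0.2, 5]. Dense output
  by cubic Hermite interpolation on each accepted step. Defaults
  `rel_tol = 1e-6`, `abs_tol = 1e-12`, chosen to match common practice in
  biochemical simulators; the output grid of `points` rows includes both
  endpoints.
* **euler**: fixed step (`fixed_step`, default 1e-3), landing exactly on
  grid points by sub-dividing each grid interval into equal steps no larger
  than the requested one. Intended for time-critical inner loops and as an
  independent cross-check of the adaptive solution.
* **gillespie**: direct-method SSA. Kinetic-law values are propensities
  and the state holds molecule counts (non-negative integers required at
  start). Output grids are sampled piecewise-constantly (the last event
  carries forward); linear interpolation would bias jump processes.
  Trajectories are bit-reproducible under a fixed seed. Model events are
  not supported in SSA runs.
* **bdf** (optional backend): delegates to scipy's BDF behind the same
  options contract for stiff problems; no event support. It is a
  convenience, not part of the package's validated core.

Events are located inside accepted steps by bisection on the dense output
to a time tolerance `1e-12 * (1 + |t|)`; all right-hand sides of the firing
events' assignments are evaluated against the pre-event state before any
target is written, and simultaneously firing events apply in document
order. Triggers are persistent; delays and priorities are out of scope.

## Steady state and structure

Conserved moieties are computed by exact rational (fraction-based) row
reduction of the stoichiometry matrix: the first r linearly independent
rows (document order) become the independent species, giving `N = L N_R`
with identity on the top of `L`, and `Γ = [−L0  I]` with `Γ N = 0` exactly.

Newton always operates on the reduced system — dependent species are
eliminated through the conservation totals — because the full Jacobian is
singular whenever conservation laws exist. Two strategies solve the Newton
systems: `exact` (dense LU) and `inexact` (GMRES to the forcing tolerance
`η_k = min(0.5, sqrt(||f||))`, the classic inexact-Newton choice); both
damp by backtracking halving (at most 20 halvings) and clip negative
species values to zero with a diagnostic rather than solving a constrained
problem. Defaults: `tol = 1e-9` on `||f||_inf`, `max_iter = 100`,
`exact` strategy. `presimulate_then_solve` integrates for a caller-chosen
time first, which selects the basin (and hence the root) of multistable
systems.

## Sensitivities

Forward sensitivities solve `s_j' = J s_j + ∂f/∂p_j` with `J` and
`∂f/∂p` built symbolically. Initial conditions are zero for rate
parameters and `e_i` for species-initial-value parameters; initial
assignments that depend on a selected parameter are not differentiated
(the zero initial condition is used), and models with events are rejected
because trigger crossings make the forward equations discontinuous.

* *simultaneous*: one augmented system of dimension n(1+m), stepped by the
  same Dormand–Prince pair with error control over states and sensitivities
  jointly.
* *staggered*: the state is integrated first; each accepted step is then
  traversed again for the sensitivities with the same tableau and its own
  adaptive substepping, evaluating `J` and `∂f/∂p` on the state's Hermite
  dense output. The state pass runs 10^3 tighter than the requested
  tolerance because the interpolant, not the step, limits the second pass.
* *finite-difference*: central differences with relative step
  `fd_step * max(|p|, 1)` (default 1e-6) and two tight-tolerance
  simulations per parameter — the independent oracle for both forward
  methods. Unknown parameter ids yield zero columns here (the oracle is
  permissive); the forward methods reject them.

Sensitivity integrations default to `rel_tol = 1e-10` so the two forward
strategies agree to ~1e-7 on sensitivities of magnitude ~30-50. One
numerical caveat worth recording: sensitivity transients contain secular
`t·e^{-t/τ}` terms (the augmented system has defective eigenvalues), so
convergence to the steady-state sensitivities needs roughly twice the
state's slowest timescale — the limit-consistency test evaluates at
10·(2τ), not 10·τ.

Scaling options: raw `∂x/∂p` (default), parameter-scaled `p ∂x/∂p`, and
fully scaled `(p/x) ∂x/∂p` (the power-law exponent).

## Control analysis

With `E = ∂v/∂x` (unscaled elasticities, amounts convention) and
`J_R = N_R E L`:

    C^S = −L J_R^{-1} N_R          (species × reactions)
    C^J = E C^S + I                (reactions × reactions)

scaled by `v_j/x_i` and `v_j/J_i` (Kacser–Burns convention — the scaling
convention is this package's choice, stated here because conventions vary
across the literature). The link-matrix formula is exact at the steady
state; the test-suite additionally verifies it against numerical 0.1%
activity scaling. Scaled quantities raise an explicit error when a flux or
concentration is zero instead of propagating NaN. Stability verdicts come
from the reduced Jacobian's eigenvalues with tolerance 1e-9 on the largest
real part, guarded by a residual check so non-stationary points are
rejected.

## Sessions and snapshots

State snapshots frame a canonical-JSON payload (model structure, state
vector, clock, globals, trigger flags, RNG state, integrator options) with
a magic tag, a format version and a SHA-256 checksum. The format is
deliberately portable across machines — a platform-specific memory dump
would be faster to write but not safely relocatable; the compile cost the
snapshot avoids is already small here, and restoring reuses the in-memory
artifact cache, so a reload never re-generates code for a structure it has
seen. Pickle support is implemented on top of the same snapshot bytes.
Parallel loading guarantees only worker-count independence of results; the
current mechanism is a thread pool, which is a contract, not a promise of
linear speedup.

## Synthetic fixtures: what they cover and what they do not

The generators produce the study systems: the two-step linear chain with
boundary source `X0 = 10` and rates `k1 = 0.1, k2 = 0.3, k3 = 0.14`
(closed-form steady state `(10/3, 50/7)` and sensitivity closed forms),
seeded log-uniform chains in [0.01, 1], a closed isomerisation pair (one
conservation law), immigration-death with `k = 10, γ = 1` (stationary
Poisson mean 10, Fano factor 1 — the SSA calibration target), a saturable
Michaelis–Menten pathway, a one-species bistable switch with roots at
0, 0.5 and 2 (recomputed by bisection at build time), and connected random
uni/bimolecular mass-action networks. The chain's first rate is `k1*X0`:
a first step proportional to `S1` with `S1(0) = 0` would freeze the chain
at zero and contradict the non-trivial sensitivity curves the model is
meant to exhibit; the literal `k1*S1` variant is kept as a parser fixture.

These fixtures are small (≤ 10 species), mass-action or single-saturation
kinetics, well-conditioned, and non-stiff. Passing tests therefore
demonstrate correctness of the algorithms on exactly characterised
systems; they do not demonstrate robustness to stiff, large, or poorly
scaled real-world models, for which the bdf backend and moiety reduction
help but are not validated here at scale.

## Problem sizes and defaults used in the checks

The packaged checks run the chain analyses on 500-point grids over [0, 40],
Euler/RK45 cross-checks at `h = 1e-4` over [0, 10] on five fixtures, 20
seeded SSA runs of length 150 (≥ 10^4 stationary samples pooled after
t = 50), control-analysis theorems on four fixtures, and a 50-model corpus
for the concurrency contract — sizes chosen so the full suite characterises
every claim while remaining quick to run routinely.

## Known limitations

- No delays, algebraic rules, event priorities/delays, function
  definitions, units validation, or hierarchical model composition.
- Compartments are constant; species with assignment rules leave the ODE
  state.
- Forward sensitivities exclude models with events; steady-state
  sensitivities cover constant parameters only.
- SSA ignores discrete events and interprets kinetic laws as propensities
  without volume corrections — the modeller owns that convention.
- The inexact Newton's GMRES is dense and unpreconditioned; it targets
  correctness and the forcing-tolerance contract, not large sparse systems.
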