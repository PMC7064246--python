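# Methods

## Model

The simulator treats resource distribution as a linear ("Ohmic") flow
network. Nodes are resources (fixed, strictly positive potential),
consumers (fixed specified flow draw) and branch points (zero draw); an
undirected link of length `L` and strength `S` has resistance `R = L/S`.
At a given per-consumer demand `I_C`, potentials satisfy the nodal
(weighted-Laplacian) equations: at every non-resource node, conducted
inflow `Σ_j (V_j − V_i)/R_ij` equals the node's draw. Consumer power is
`P_Ci = I_C · V_Ci`; transport loss on a link is `I²R`; total network
power is `Σ_i P_Ci`. Energy balance (resource output = consumer power +
losses) and flow conservation are consequences of the nodal equations and
are asserted, not assumed, in the test suite.

Assumptions worth keeping in mind:

* The flow law is linear and steady-state; there is no storage, no time
  stepping, and no capacity limit on links.
* Consumers are pure sinks with passive pass-through: a consumer may relay
  flow to others but never generates it. In the nodal model this needs no
  extra rationing logic — it is exactly the fixed-draw boundary condition.
* Negative consumer potentials and powers are meaningful states, not
  errors: they appear when demand is pushed past what the architecture can
  supply and are what terminates the demand sweep.
* All quantities are in generalised dimensionless units. The model is an
  analogue for any of the linear phenomenological flow laws, so no unit
  system is imposed anywhere.

## Solver

`direct_solve` reduces the system to the non-resource block: a sparse
symmetric Laplacian over consumers and branch points, with resource
potentials entering through boundary conductances, solved by
`scipy.sparse.linalg.spsolve`. It is the package's oracle: exact to linear
solver precision.

`solve_fixed_demand` is the iterative load-flow scheme: compute the
mismatch between specified and received flow at every demand node, solve
the conductance (Jacobian) system for the counteracting potential
adjustment, repeat until the worst mismatch is below the threshold
(default 0.001 flow units, configurable via `SolverConfig`). For a linear
flow law the correction is Newton's method and lands on the direct
solution in one update; the loop and the mismatch threshold are retained
because they are part of the method's contract, and the equivalence of the
two paths (≤1e−6 in every potential) is tested on a population of 100
random networks.

`sweep` exploits linearity: with strengths fixed, `V(I) = V0 − I·W`, where
`V0` solves the zero-demand system and `W` the unit-demand system. Two
sparse solves therefore produce exact solutions at every grid step; the
tests verify grid records against both solve paths. The default schedule
(start 1, step 0.1, ceiling 1000 flow units per consumer) stops early at
the first record with negative total power, which is included and flagged.
Peak detection is a grid argmax with ties broken toward lower demand; its
resolution is one grid step, which is also the tolerance used when
checking the half-potential property.

Degenerate inputs: consumers with no path to a resource raise a
singular-system error naming the nodes (validation catches this before
assembly); zero demand is a valid solve (flat potentials for a single
resource) but effective resistance is undefined there and raises.

## Generators and study conditions

* **Random spatial networks.** Consumers, resources and optional branch
  points are placed uniformly in the topology (plane side or sphere radius
  auto-sized as `10·nC · 100·nR` unless given); every node pair except
  resource–resource receives a link with probability `1 − pNoConnection`;
  lengths are Euclidean, strengths 1. Generation retries (fresh draws,
  logged) until all consumers and branch points are reachable — only
  connected networks are meaningful to solve.
* **Radial burst.** One central resource, `nC` consumers on spokes of
  identical length and strength: the zero-`σ_RE` reference architecture.
* **Fully branched.** A self-similar tree with a consumer at every
  junction; level `l` (0 nearest the resource) holds `f^(l+1)` consumers
  (default branching factor 2, eight levels, 510 consumers). Link lengths
  are set per level, halving with depth, rather than Euclidean — branched
  families are defined by their link lengths, not by topology size.
* **Evolved branching.** Starts from a near-radial burst of 512 consumers
  at slightly jittered radii `D·(1+u)`, `u ~ U(0, 0.05)` (the jitter makes
  the base carry a small structural inequality). Stage `k` inserts levels
  `1…k` of zero-demand branch points: level `j` sits at path radius
  `D(1 − 2⁻ʲ)` at the mean angle of its consumer group, with set trunk
  lengths `D/2ʲ`; the deepest level connects to consumers by the radial
  remainder. At the final stage (7 levels) the consumer hop uses the set
  self-similar length `D/2⁷`, so every consumer sits at path distance `D`
  exactly — equal path distances despite unequal Euclidean radii — and
  power inequality vanishes. Consumer count and positions are identical at
  every stage; total link length strictly decreases with stage by
  construction (verified in tests). The placement rule is this package's
  own choice: any placement achieving equal final-stage path lengths
  realises the same endpoint.
* **Strength rule.** Branching families set link strength to
  (downstream consumer count)^exponent, default exponent 2. With uniform
  demand, tree-link flow is exactly `I_C ×` downstream count, so this
  realises `S ∝ I²` statically from topology and makes per-link loss
  `I_C²·L`, a function of link length alone. It is applied once, from
  topology, and strengths stay fixed for the sweep: re-fitting `S` to
  solved flows at every step would make losses flow-independent and erase
  the power peak the sweep exists to find.

**Resource potentials.** Raising or lowering `V_R` rescales all consumer
potentials linearly, so it is a free presentation choice; the generators
calibrate it so the power peak lands at a target demand of 100 flow units
per consumer, mid-grid on a log scale (the evolved-branching experiment
targets 300 on its final stage so the earliest stages, whose effective
resistance is ~100× larger, still peak inside the grid). The calibration
uses one probe solve: `R_E` is independent of `V_R`, so
`V_R = 2 · I_target · R̄_E`. Multi-resource example networks use equal
resource potentials; the σ-identities are exact algebraic statements under
equal (or single) resource potentials and the mean-resource form of
`R_E`.

**Standard deviations** use the population (divide-by-n) convention; the
identities `σ_VC = σ_RE·I` and `σ_PC = σ_RE·I²` are exact only under one
consistent convention, and this is the one the derivations use. A
`sample=True` flag is available throughout for the ddof-1 convention.

## What the synthetic networks do and do not show

The generators produce the idealised architectures the framework
reasons about — uniform spatial scatter, perfect radial symmetry, exact
self-similar trees. They do not emulate real distribution networks: no
correlated node placement, no heterogeneous demands, no capacity
constraints, no noise on link properties, no temporal dynamics or
diminishing resource potentials. Passing tests therefore demonstrate the
internal consistency of the framework (conservation laws, the
half-potential peak, the σ-identities, the branching orderings) on its own
stated conditions — not that any empirical network obeys the linear flow
law.

## Numerical choices

* Solver mismatch threshold 0.001 flow units; iterative/direct agreement
  tested at 1e−6; conservation laws at 1e−6 relative; affinity of `V(I)`
  and flow-invariance of `R_E` at 1e−9.
* "Exactly zero" spread claims for symmetric architectures are asserted as
  bit-identical consumer values (`ptp == 0`); the standard deviation of
  mathematically identical values is additionally bounded at 1e−12
  relative, the round-off floor of averaging identical floats.
* Ratio-targeted selections (the 0.75/0.50/0.25 dispersion analysis) use
  nearest-record matching, never interpolation, so consumer-level samples
  are always states the solver actually produced.
* Tie-break at the power peak: lowest demand. Degenerate zero-σ reference
  samples in the dispersion normalisation are defined as all-zeros.
* The auto-sizing rule `10·nC · 100·nR` is read as a product. The
  connection-matrix CSV convention: entries are link strengths, absent
  links hold the `noConnection` placeholder, lengths come from endpoint
  coordinates.

## Problem sizes

The shipped experiments and acceptance run use six example networks of
20–64 consumers (sweeps of ~2000 steps each, subsecond in total), the
512-consumer evolved-branching sequence over stages 0–7, and the
510-consumer fully branched tree. These sizes keep every documented
analysis comfortably reproducible on a laptop while being large enough for
the level structure (8 distinct potential levels, 7 branch stages) to be
fully expressed.

## Known limitations

* Linear flow laws only; no nonlinear force–flux relations.
* Single-valued, time-constant resource potentials (no diminishing
  resources).
* Branch-point placement in evolved branching is a geometric convention,
  not an optimisation; river-network or vascular-realistic geometries are
  out of scope.
* The Gini coefficient is provided as an untested convenience only — it is
  scale-blind, which is precisely the argument for σ-based measures here.
* Rectangular (non-square) planes are not supported in the parameter file.
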