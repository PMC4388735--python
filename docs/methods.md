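# Methods

## Model representation

A `StoichModel` holds species (with a boundary flag) and reactions with
stoichiometry, reversibility, bounds, objective coefficients, and optional
gene–protein–reaction (GPR) rules.  Boundary species are excluded from the
steady-state balance: the stoichiometric matrix **N** has one row per
internal species, and exchange reactions appear simply as columns with a
nonzero net elemental balance.  All coefficients, bounds and fluxes are
`fractions.Fraction`; floating-point input is converted through its
shortest decimal representation (`0.5 → 1/2`, `12.77 → 1277/100`), so the
pipeline's combinatorial claims (vertex counts, module membership, support
sizes) never depend on a tolerance.  Unbounded bounds are `None`, not a
big number.

Reversible-reaction splitting replaces each reversible reaction by a
forward copy and a backward copy with negated stoichiometry and negated
objective coefficient, bounds `[0, ub]` and `[0, −lb]`.  The feasible net
fluxes are unchanged; the flux cone becomes pointed, so every
non-decomposable optimal route is a vertex and linealities vanish.

## Exact linear programming

`lp_core` implements a two-phase primal simplex on dense rational
tableaus with Bland's anti-cycling rule.  Bounded variables are reduced
to standard form by shifting (finite lower bound), reflection (upper
bound only), or a difference of nonnegatives (free).  Phase 1 drives
artificials out of the basis and drops redundant rows; phase 2 detects
unboundedness and returns a recession-direction certificate.  Solutions
are basic, feasible with zero residual, and the FVA and module-interface
routines compare endpoint values with `==`.

This is deliberately a from-scratch exact solver rather than a
floating-point LP with a rational clean-up: the problems in scope (the
toy network, module-sized submodels, and property-test fixtures of a
dozen reactions) are tiny, and a single code path is easier to trust
than a repair loop.  The test suite cross-checks the optimum against
scipy's HiGHS on random models and verifies strong duality against an
explicitly constructed dual.

Pathway-length minimization is the one mixed-integer step.  The
formulation is the standard big-M indicator model (minimize Σ yⱼ subject
to |Jⱼ| ≤ Mⱼ yⱼ, steady state, bounds, objective pinned at *Z*\*), with
Mⱼ taken from the exact FVA interval at the optimum.  Branch-and-bound
runs in HiGHS via `scipy.optimize.milp`; the selected support is then
certified exactly by forcing its complement to zero and re-solving the
rational LP, and the reported count comes from the exact witness.  Where
FVA is unbounded (cycle directions), Mⱼ falls back to a cap
(default 1024, configurable): a support-minimal optimum never rides a
cycle — removing a cycle component can only shrink the support — so any
cap above the cycle-free flux magnitudes is safe; the witness certificate
holds regardless.

## Vertex, ray and lineality enumeration

`polyhedra.double_description` computes the generators of
{y : **E** y = 0, **B** y ≥ 0} exactly: starting from the nullspace of
**E** as the lineality basis, each inequality either cuts the lineality
space (one basis vector is promoted to a ray and the rest are projected
onto the hyperplane) or triggers a classic double-description step, where
adjacent positive/negative ray pairs are combined.  Adjacency is decided
combinatorially from tight-constraint sets; rays are kept as primitive
integer vectors.  Polyhedra {**A** x = b, lb ≤ x ≤ ub} are homogenized
with a variable λ ≥ 0: generators with λ > 0 scale to vertices, λ = 0 are
recession rays.

When a lineality space exists (non-split models), "vertices" stand for
the minimal faces, which are translates of that space; representatives
are canonicalized by reducing to zero the lineality pivot coordinates,
with pivots chosen on the *highest*-index coordinates so that flux
concentrates on the earliest reactions.  On the toy network this keeps R2
active in every vertex representative and places {R3, R4} in the
lineality, and it makes the shortest non-split optimal route an exact
convex combination of two vertex representatives.  Any other
representative choice is equally valid — the counts are invariant — but
this one is fixed for determinism.

Worst-case double description is exponential; that is acceptable here
because enumeration is only ever applied to flux modules ("a few, small
segments" of the network) and to desk-scale fixtures.  The test suite
checks the enumeration against a brute-force oracle that pins every
subset of variables at finite bounds, solves the square systems exactly,
and keeps the feasible solutions.

## Flux modules

At the optimum, reactions split into a fixed part (zero-width exact FVA
interval) and a variable part.  Candidate modules are connected
components of the variable reactions in the species–reaction graph
(boundary species do not connect).  Each component is then *verified*:
for every species it touches, the net production by the component is
minimized and maximized over the optimum with two exact LPs; all-constant
values certify the component as a module with interface **d** (essential
iff **d** ≠ 0).  Components that fail are merged with the other failing
components and re-verified to a fixed point — for species balanced
entirely against the fixed network the verification cannot fail, so the
loop terminates immediately on all shipped fixtures.  Correctness
therefore rests on the verified property itself, not on the discovery
heuristic.

Each essential module is extracted into a submodel: its reactions and
species, plus a unit-flux input pseudo-reaction supplying the net-consumed
interface species and a unit-flux output pseudo-reaction draining the
net-produced ones; a dummy species produced by the input and consumed by
the output forces both to run.  Interface magnitudes are expressed at the
fixed optimum value *Z*\* (recorded in the decomposition as the scaling
convention).  If a module contains objective reactions, their (constant)
contribution is pinned by a reporter species and a fixed-flux reporter
reaction.  Module bounds are kept, so a second flux constraint cutting
through a module appears as a polytope facet and module vertices may be
convex combinations of optimal-yield EFMs — the intended behavior under
multiple restricting constraints.

The whole-space description combines per-module vertex lists (counts
multiply; the sum is what was actually enumerated), whole-model extreme
rays, and the lineality basis (nullspace of **N** over the fully
unbounded columns).  "Subnetworks" are the modules with ≥ 2 vertices —
the ones that actually contribute alternatives; the toy model has 3
modules of which 2 (non-split) or 3 (split) are subnetworks.  Minkowski
membership (`decompose_in_space`) first checks optimal-feasibility
exactly, returning a violated-constraint certificate on failure, then
finds weights by exact LP feasibility.

## Elementary flux modes

EFMs are enumerated as the extreme rays of the split flux cone
{v ≥ 0 : **N** v = 0} (numeric bounds play no role) with the same double
description engine, then mapped back through forward-minus-backward.
Two-cycle modes collapse to zero and are dropped; fully reversible modes
appear in both orientations and are reported once, in the direction
making the first nonzero coordinate positive.  Calling the enumerator on
an already-split model keeps the two-cycles, matching the convention
that each split pair is an EFM of its own.  EFMs containing the (single)
objective reaction are normalized to unit objective flux, others to
primitive integers.  A size guard (40 split reactions) keeps plain
enumeration at module/toy scale.

The optimal-yield filter scales each mode to saturate the restricting
nonzero bounds and keeps those attaining *Z*\*; modes with zero objective
flux are non-operational and always excluded.  With more than one
restricting constraint the criterion is only necessary, and a warning is
emitted.

Support-minimality is certified by the rank test: nullity of **N**
restricted to the support columns must be 1.  Rank is computed by
fraction-based Gaussian elimination so the verdict is tolerance-free; a
singular-value variant (`rank_test_svd`, tolerance 1e−9) is provided as
an optional floating-point cross-check.

## Secondary objectives

*P_L* counts nonzero fluxes (exact zero test; a documented threshold,
default 1e−9, applies only to externally supplied floating fluxes).
*P_J* = Σ|Jⱼ| and *P_C* = Σ cⱼ|Jⱼ| are linear on split models and are
minimized by exact LP there.  Costs cⱼ come from GPR rules: AND sums
protein lengths (a complex needs every subunit), OR takes the minimum,
maximum or average (isozymes); the result is divided by the mean length
over all proteins referenced by the model, so cⱼ < 1 flags a
cheaper-than-average enzyme.  Reactions without annotation get cⱼ = 1,
and the "equal" rule reduces *P_C* to *P_J*.  The normalization by the
corpus mean is a design choice; any positive scaling yields the same
minimizers.

On split models the minimum of each secondary objective is attained at a
vertex, and `vertex_statistics` scores every reconstructed vertex
(lazily; above 100 000 combinations a seeded uniform sample) so
ties are counted exactly rather than silently broken.  On non-split
models the shortest route can be strictly shorter than every vertex —
opposed fluxes cancel in convex combinations — which the toy network
demonstrates (minimum 11 versus vertex minimum 12).

## Fixtures

`build_toy_model` is the 18-species/18-reaction network: a capped input
X→A, a reversible triangle A↔B (directly, or via C), a linear trunk to a
branch point D where two alternative routes (one of three steps, one of
two) each convert D + ADP → H + ATP, a second branch point I feeding J
and L (directly or through the reversible chain J↔K↔L), condensation
J + L → M, an ATP-consuming step M + 2 ATP → N + 2 ADP, and output N→Y.
Its validity certificate is joint: one fixture simultaneously reproduces
optimum 1, 13 EFMs (12 optimal-yield), 4 non-split and 12 split vertices,
0/7 rays, 1/0 linealities, 2/3 subnetworks, and minimal *P_L* 11 (one
constraint) and 12 (after adding J₁₅ ≤ ½).

`generate_random_model` emulates small metabolic networks for property
tests: internal species on a substrate→product backbone (guaranteeing a
nonzero steady-state route and reachability of every reaction from the
input), decorated with random conversions with coefficients in {1, 2} and
a configurable reversible fraction (default 0.3), one input exchange
capped at 1 and one output exchange carrying the objective.  Draws are
seeded and deterministic; infeasible draws are resampled up to a retry
cap.  These fixtures exercise the combinatorics the package is about —
alternative routes, cycles, split pairs — but deliberately not
genome-scale features: no cofactor coupling across distant modules, no
compartments, no blocked subnetworks, and sizes small enough for
brute-force oracles.  Passing tests certify the algorithms' correctness
on pointed and non-pointed polyhedra at small scale, not performance or
numerical behavior on genome-scale reconstructions.

## I/O

The tabular dialect is one reaction per line —
`id : 2 A + B <=> C ; lb, ub ; obj ; gpr` — with `@boundary` and
`@species` directives fixing species order, rationals as `p/q`, and
`inf`/`-inf` for unbounded; round-trips are exact.  SBML Level 3 models
are read and written through libsbml with the FBC package (bounds as
parameters, objectives as flux objectives, GPRs as gene-product
associations); since SBML stores doubles, decimal values round-trip
exactly but non-decimal rationals (e.g. 1/3) are serialized at double
precision.  Reports are JSON and TSV with rationals as `p/q` strings;
decimals appear only in human-readable summaries.

## Known limitations

- Vertex products are counted and iterated lazily but never materialized;
  genome-scale enumeration (hundreds of modules, thousands of reactions)
  is out of scope for the shipped exact simplex, which has no
  floating-point fast path.
- EFM enumeration is restricted to module/toy scale by the size guard.
- The MILP lower bound relies on HiGHS branch-and-bound over a float
  relaxation; only the witness (upper bound) is certified exactly.  Tests
  cross-check the optimum against vertex enumeration on split models.
- The optimal-yield EFM filter is heuristic under multiple restricting
  constraints (warning emitted).
- GPR cost vectors model synthesis cost only; protein lifetimes and
  expression regulation are out of scope.
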