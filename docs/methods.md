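# Methods

## Model representation

A compartmental model is a finite directed multigraph. Each vertex is a
compartment identified by an ordered tuple of level labels — length 1
for an atomic model, one coordinate per factor for a product. Tuple
identity is authoritative; display names (`S_1`, `I_FAU`) are derived by
a naming convention (per-position subscript tokens plus optional
explicit names) and exist only for rendering and for the state symbols
of the ODE system. Two per-model sentinels, SOURCE and SINK, carry
recruitment inflows and removal/mortality outflows; they are not
ordinary vertices and never contribute coordinates to product tuples.

Arc rates are sympy expressions whose free symbols are classified,
relative to the owning model, as parameters, state symbols (display
names of compartments), or aggregate symbols. An aggregate is a declared
shorthand for a sum of compartments (typically a population size
`N = S + I`); it is kept symbolic in generated output and expanded
before any comparison or numeric evaluation. Each arc also records its
*interaction arguments*: the non-source compartments its rate depends on
(the infective compartment of a transmission term). Argument order is
structural — it fixes the subscript order of product parameters — and is
inferred from the rate (display-name order) when not given explicitly.

Parallel arcs are first-class: a product generates one arc per generating
mechanism, and `aggregate_parallel_arcs()` is an explicit
canonicalization that merges each parallel bundle into a single arc with
the summed rate and merged provenance. The operation is idempotent and
preserves every compartment's symbolic net flow, so it never changes
dynamics; both forms are useful (the multigraph form for audit and
diagrams, the merged form for compact equations and for stochastic
simulation, where parallel arcs would otherwise double-count
propensities).

## Product operations

All compartmental products run through one n-ary engine. Factor `f`
occupies a fixed slice of the product label tuple; "descendant of a
factor compartment" means agreeing with it on that slice, and an arc's
*levels* are the coordinates outside the slice of the acting factor(s).

**Singleton (Cartesian) arcs.** For each factor arc with source `X_s`,
target `X_t`, and interaction arguments `Z_1..Z_k`, the engine iterates
over every descendant `x_s` of `X_s` and every independent choice of
descendants `z_j` of each `Z_j`, emitting an arc from `x_s` to the
descendant of `X_t` on the same levels as `x_s`. The crucial point is
that the `z_j` range independently of the source's level — that is what
turns `beta*S*I` into the full matrix of cross-level terms
`beta_ij*S_i*I_j`. Inflow (SOURCE) arcs are anchored at the target's
descendants instead, which differentiates recruitment by the receiving
compartment's levels (e.g. vertical-transmission and immune-at-birth
inflows in the aged SIR model). Per factor arc with `k` arguments this
yields `(other levels)^(k+1)` product arcs, a count the test suite
verifies against exhaustive enumeration on random factors.

**Parameter subscripting.** By default every parameter in a factor rate
is subscripted by the full level tuple: the source's levels first, then
each argument's levels in argument order. This reproduces the
conventional namings (`beta_ij` with i = susceptible's community,
j = infective's community; `gamma_i`; `Lambda_i`). A `ProductRule` can
override per base via `subscript_selector`, choosing which positions of
the level tuple each parameter keeps — the four-factor gonorrhea model
uses `beta: genders only`, `c: susceptible's gender+risk`,
`p: both sides' gender+risk`, `gamma: exposure only`, which yields the
transmission shape `S_abc * c_bc * sum(beta_be * p_bcef * I_def / N_def)`.
Collapsing a subscripted family back to one undifferentiated symbol
(all `gamma_i -> gamma`) is done by substitution and is regression-tested.

**Aggregates in products.** A factor aggregate appearing in a rate must
be re-scoped. The default policy follows the arc's first interaction
argument: the aggregate becomes `N_<levels of z1>` with scope equal to
the matching descendants, giving per-group prevalences such as
`I_M / N_M`. The alternative `"global"` policy sums over all descendants
of the factor scope; it is the right choice when both factors classify
the same individuals (two strains infecting one population), where the
population size is the whole state space. The choice is per aggregate
base in the `ProductRule`; no single rule covers both situations, since
it depends on whether the other factor partitions the population or
refines each individual's state.

**Strong products.** In addition to all singleton arcs (which are
exactly the extended Cartesian arcs), the engine emits one diagonal arc
per admitted *set* of transitions from distinct factors: the source must
descend from all member sources, the target from all member targets, and
the j-th argument slot of the combined rate is constrained by the j-th
argument of every member that has one. Sets of any size up to the number
of factors are generated (only pairwise sets are exercised by the
reference models); sets touching SOURCE/SINK arcs are excluded by
construction, and `simultaneous_set_policy` is the hook for biological
exclusions — the two-strain SIS entry admits only transmission-pairs,
which drops both transmission-with-recovery and recovery-with-recovery
combinations (the latter is a package choice; the co-transmission
literature motivates the former). The default combined rate is a *fresh*
parameter (named `base__<factor indices><levels>`, the double underscore
standing for bracketed-set notation) times the source and argument
states, divided once by each aggregate appearing in the member rates; no
algebraic relation to the singleton parameters is assumed, because none
is implied by the construction.

**n-ary products and families.** `n_ary_product` applies the engine to
all factors at once, with flat label tuples. This is equivalent, up to
parameter naming, to folding the binary product (the engine accepts
factors whose labels are already tuples, so products of products work),
and the package tests structural isomorphism between the direct and
folded forms on random factors. The direct form is preferred because
per-parameter subscript selection needs to see the full level tuple at
once. `enumerate_partial_products` builds the `2^k` models over subsets
of optional factors in binary-counting order, the raw material for
structural sensitivity analysis. Isomorphism checking for these
properties is structural — compartment tuples and the (source, target)
arc multiset under a coordinate permutation; rates correspond under the
induced subscript renaming, which is checked on the reference models
rather than re-derived generically.

**Linear products.** `linear_cartesian` verifies that each factor is in
the linear class (every rate a state-free coefficient times its source,
inflows constant, no aggregates, no interaction arguments) and then runs
the same engine; with undifferentiated numeric rates and no sources the
product transition matrix equals the Kronecker sum `M_A ⊕ M_B`, which an
independent numpy `kron` oracle confirms over random factors. Nonlinear
factors are rejected with a pointer to `extended_cartesian`.

## Dynamics

`ode_system` assembles `rhs(X) = Σ inbound − Σ outbound` (total rates,
SOURCE/SINK flows included), in deterministic sympy-canonical term
order. For a closed model (no SOURCE/SINK arcs) the symbolic total
derivative is identically zero, checked per reference model.
`compare_odes` expands aggregates on both sides, applies an optional
state bijection, and tests semantic equality per compartment; semantic
equality itself is rational-function normalization (common denominator,
expand, cancel), decisive for the rational rates that occur here, and is
cross-checked in tests against evaluation at random numeric points.

`integrate` uses `scipy.solve_ivp` with LSODA (adaptive, stiff-capable —
products with many levels, compartmental aging especially, produce stiff
systems) at rtol 1e-8 / atol 1e-10 by default; unbound symbols are
reported by name before any numeric work. `jump_realization` is the
Gillespie direct method on the canonical (parallel-arc-merged) model,
with a mandatory seed feeding a `numpy` Generator and an event log of
(time, arc); a negative evaluated propensity aborts with the state
snapshot. Time-averaged occupancies are computed with proper
time-weighting of the piecewise-constant path.

## Reference models and the synthetic conditions

The zoo's factor models use the standard textbook forms: SI
(`beta*S*I`, removal `gamma*I`), SI/SIS with demography
(`Lambda` inflow, `mu` per-capita mortality, frequency-dependent
`beta*c*p*S*I/N` for STI models), closed SIR, three-class compartmental
aging (aging rate `alpha`, age-specific mortality `mu_k`, the oldest
class aging out), two-state risk mobility (`rho`, `sigma`), a static
gender partition, tuberculosis (fast/slow progression split by `p`,
reactivation `nu`), and leprosy (two infectious forms with transmission
coefficients `b`, `c` and progression `theta`, `phi`). None of the
classical sources fix numeric parameter values for these constructions,
so all numeric checks are property-based: conservation, closed-form
limits (the logistic SI solution when removal is zero, pure exponential
decay when transmission is zero), the Kronecker-sum identity, and the
immigration–death stationary mean `Lambda/mu` (run at `Lambda=50`,
`mu=1`, 10^4 events, tolerance three standard errors with the standard
error taken from the process's known variance `Lambda/mu` and
autocorrelation time `1/mu`). Random structural trials use factors of
1–5 states with Bernoulli(0.5) transitions — large enough to exercise
every combinatorial branch, small enough that the whole suite runs in
seconds.

Two zoo choices are package decisions where the constructions are
genuinely open: the exposure (screening) factor's enrollment/drop-out
rates `eta`/`delta` are free symbols with two-way movement, and the
joint leprosy–tuberculosis product attaches free cross-immunity
multipliers (`chi_<leprosy state>` on TB transmission, `xi_<TB state>`
on leprosy transmission) to product transmission arcs whose source is
not fully susceptible to the other disease; no numeric claim is made for
either. Product SINK outflows are subscripted by the full level tuple of
the departing compartment, mirroring the treatment of inflows.

These synthetic constructions exercise the algebra, not epidemiology in
the field: passing tests show that the products generate exactly the
intended structures and equations, not that any parameterization fits
observed data (model fitting is out of scope).

## Numerical and degenerate-input choices

Arc ordering is deterministic (generation order; canonicalization sorts
lexicographically by endpoints, rate, and provenance), so DOT output and
ODE term order are reproducible byte for byte. Substitution prunes arcs
whose rate simplifies to zero (e.g. same-gender partner probabilities
set to zero) as a canonicalization step after generation, never during
it. Empty models yield empty ODE systems; a product of one factor is
that factor; a single-compartment, arc-free factor acts as a unit up to
one extra subscript. Subscript tokens are concatenated when all are
single characters (`beta_12`) and underscore-joined otherwise; level
tokens are assumed not to collide under this rendering (all shipped
models use single-character tokens). The rate-string parser accepts
identifiers, `+ - * / **`, and parentheses, and maps every identifier to
a plain symbol — `I` is a state, never the imaginary unit; `lambda`
cannot be used as a parameter name (Python tokenizer keyword), so the
recruitment rate is spelled `Lambda`.

## Known limitations

* Product state spaces are always the full Cartesian product; models
  needing only a subset of it (state refinements that apply to some
  compartments only) or history-dependent state (order of infection)
  are out of scope.
* Age structure is compartmental only; no PDE (transport-equation)
  representation.
* No parameter estimation or fitting, and no bifurcation analysis; the
  family enumeration produces the candidate models, evaluating them
  against data is the user's problem.
* The strong product's combined rates are deliberately uncommitted
  (fresh parameters); users who want, e.g., a co-transmission rate tied
  to the singleton rates must supply a `combined_rate` policy.
* `is_isomorphic` compares structure, not rates, so it certifies
  isomorphism of diagrams; rate correspondence under renaming is only
  verified on the shipped reference models.
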