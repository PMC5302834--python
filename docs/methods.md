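# Methods

## Producibility semantics

Topological producibility is forward reachability on the bipartite
reaction–metabolite graph with AND-semantics on reactants: a directed
reaction fires iff *every* reactant is already producible, and a metabolite
is producible iff it is a seed or a product of a fired reaction. The scope
is the least fixed point of this relation; the implementation is queue-based
(per-reaction counters of unsatisfied reactants), linear in the number of
arcs, and provably order-independent — property tests shuffle the reaction
order and assert identical fixed points.

Three deliberate choices:

* A reaction with no reactants fires unconditionally (vacuous universal
  quantifier), which is the literal reading of the fixed-point relation and
  makes import-style reactions behave sensibly.
* Stoichiometric coefficients and SBML boundary flags are ignored by scope;
  they matter only to the LP layer.
* Cycles never self-start. This is the substantive difference from
  cycle-tolerant topological semantics: under AND-reachability, a cycle whose
  members are produced only by cycle reactions stays dark until some seed or
  external reaction breaks it. The branch/cycle fixture network pins both
  directions of the resulting disagreement with FBA: a stoichiometric branch
  `S → n·a + b` makes T1 FBA-producible only for n = 2 while scope accepts
  any n (scope over-approximates), and the loop `j → 2k, k → l, l → j` can
  carry steady-state flux that nets one k per turn although scope never
  reaches it (scope under-approximates).

## Gap-filling solver

The optimization has a two-stage lexicographic objective. First the
achievable target set is fixed: a target is *reconstructable* iff it is in
the scope of draft ∪ database; monotonicity of scope in the reaction set
makes this the unique maximal choice, so the stages cannot conflict (the
solver asserts, rather than assumes, that every returned completion covers
exactly this set). Then the number of database reactions is minimized.

Encoding: binary selection x_r per candidate database reaction, binary
firing z_d per directed reaction (z_d ≤ x_parent for database directions,
z_d ≤ y_m for every non-seed reactant m), binary support arcs w_{d,m} per
(reaction, product) pair with y_m ≤ Σ w_{d,m}, and a continuous level
ℓ_m ∈ [0, N] with ℓ_m ≥ ℓ_{m'} + 1 − N(1 − w_{d,m}) for every reactant m' of
d. The level ordering makes the chosen support acyclic, so MILP-feasibility
coincides exactly with topological producibility; any true completion is
feasible with BFS-layer levels. The program is solved by HiGHS
(scipy.optimize.milp) at `mip_rel_gap=0`, and every returned set is
re-verified by an actual scope computation.

Before encoding, the space is pruned soundly: only directions that fire
under the full database can ever fire, and only reactions backward-reachable
from the gap targets can appear in a *minimal* completion.

Enumeration, union, intersection:

* enumeration fixes |x| = k (the optimum) and adds one exclusion cut
  Σ_{r∈sol} x_r ≤ k−1 per found solution until infeasible — exhaustive
  because every feasible k-set is cardinality-minimal (a smaller working
  subset would contradict optimality of k; the same argument gives
  subset-minimality of every solution);
* the union is grown by iterative refinement — each solve must pick at least
  one candidate outside the union found so far, so at most |union| solves;
* a reaction is in the intersection iff forbidding it (x_r = 0) at |x| = k is
  infeasible; only members of one optimal solution need testing.

Conventions: a reversible database reaction costs 1 and grants both
directions (the objective counts reactions, and SBML declares reversibility
per reaction); solutions are sorted lexicographically by their sorted
reaction ids so output is byte-stable; identifier matching is exact string
equality; duplicate ids shared by draft and database must be content-identical
and the database copy is dropped. Seeds or targets absent from every
reaction are kept as isolated metabolites — such a target is simply reported
unreconstructable, which is a meaningful result, not an input error.

## Flux validation

The LP layer builds a stoichiometric matrix over non-boundary metabolites,
adds one import exchange per seed with bounds [0, 1000], and uses default
bounds ±1000 (reversible) / [0, 1000] (irreversible); all bounds are
configurable and the classification is invariant under uniform bound
scaling (tested). FBA maximizes the objective flux; an infeasible LP is
reported as optimum 0 with a flag rather than an exception.

Classification runs FVA over the region with a biomass floor v_bio ≥ δ
rather than at the FBA optimum, encoding "non-zero biomass production"
without tying the classification to the optimum's degenerate face. Defaults:
δ = 1 flux unit, LP tolerance 1e-6 — an explicit tolerance keeps the
blocked/essential boundary reproducible across solvers, since FVA extrema
are only computed to solver precision. Essentiality of a reversible
reaction means the interval [lo, hi] excludes 0, i.e. |v_r| > 0 everywhere,
not that a particular direction is forced. FVA essentiality is
cross-checked two independent ways in the tests: a knock-out oracle (pin
v_r = 0, re-run FBA) and cobrapy+GLPK interval-by-interval.

## Degradation benchmark

The harness emulates curation loss on a reference network: draw a random
biomass variant by independently zeroing each precursor coefficient with
probability p (Bernoulli, resampled if all vanish; default p = 0.3),
re-classify every reaction with respect to that biomass, then remove the
same fraction from each class — counts rounded half-away-from-zero per
class, the largest class adjusted by ±1 so the global count is exact —
optionally resampling (≤100 deterministic substreams) until the degraded
model cannot produce biomass. Gap-filling uses the intact reference as the
repair database and the biomass reactants as targets; the network is filled
with the union of all minimal completions, and the evaluation reports
essential-reaction recovery, post-fill FBA functionality, the 3×3
classification-drift matrix and a four-way category (functional / all
essentials recovered / one missed / several missed).

One theorem anchors the evaluation and is asserted on every fixture: any
subnetwork of the reference that produces biomass must contain every
reference-essential reaction, because essentiality *means* non-zero flux in
every biomass-producing flux distribution.

## Synthetic data

The fixture generators cover what the benchmark needs and no more:

* the worked-example instance and the branch/cycle semantics network are
  frozen by content checksums;
* planted chain instances move a random cut of 1–3 chain reactions into the
  database with 1–`width` interchangeable variants each, so the optimum,
  the full solution list (the product of variant choices) and the forced
  reactions are known in closed form; distractors are either never-firable
  (they consume a fresh unproducible metabolite) or redundant duplicates of
  surviving draft reactions, exercising both pruning paths;
* the benchmark model (default 101 reactions) composes per-module essential
  trunk chains, parallel alternative branches and dead-end blocked
  appendages into an FBA-functional whole with a designed 40/30/30 class
  split.

These fixtures are idealized: irreversible unit-coefficient reactions,
single-compartment, no cofactor coupling, and alternatives that are
perfectly symmetric. Passing the suite therefore demonstrates correctness
of the algorithms (exactness against brute force, the essentiality theorem,
determinism), not field performance on repository-scale models, where
database size, reversibility and cofactor structure dominate difficulty.
Scale is configurable; the default benchmark preset (1 network × 4 fractions
× 3 seeds on the ~100-reaction model) is desk-sized by design, and the
published-scale experiment (thousands of degraded genome-scale networks
against a MetaCyc-sized database) is a preset away but requires external
model files and cluster time.

## Numerical and degenerate-input choices

* MILP: zero relative gap; big-M equals |metabolites|+1, small enough at
  these scales to be numerically safe; every solution re-verified by scope.
* Instances with nothing to fill return optimum 0 with the single empty
  solution; unreconstructable targets are excluded before minimization and
  reported separately.
* LP tolerance 1e-6 throughout; "functional" means optimum > δ.
* All randomness flows through numpy Generators seeded explicitly; retries
  use spawn-style `[seed, attempt]` keys so determinism survives resampling.

## Known limitations

* No GPR associations, compartments, transport semantics or SBML fbc
  objectives; objectives are named explicitly.
* Weighted or likelihood-scored completion and subset-minimal (rather than
  cardinality-minimal) enumeration are out of scope.
* Enumeration cost is proportional to the number of optimal solutions,
  which can be combinatorially large on pathological instances; the
  `enumeration_limit` option truncates with an explicit flag, and union /
  intersection avoid enumeration entirely.
* The MILP encoding's arc constraints grow with Σ_d |reac(d)|·|prod(d)|;
  very large hub reactions would warrant a lazy-constraint scheme.
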