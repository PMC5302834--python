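# topofill

Topological gap-filling of draft genome-scale metabolic networks.

Draft metabolic networks reconstructed from incomplete or poorly annotated
sequence data — the normal situation for non-model organisms — are missing
reactions, so compounds the organism demonstrably makes (biomass precursors,
secreted metabolites) cannot be produced *in silico*. `topofill` completes
such drafts from a reference reaction database using a purely **topological**
producibility criterion, deliberately ignoring stoichiometric balance, which
is unreliable for cofactors and for loosely curated databases.

## The model

A network is a bipartite directed graph G = (R ∪ M, E) over reactions R and
metabolites M, with reac(r) and prod(r) the reactant and product sets of a
reaction. Given seed nutrients S ⊆ M (the growth medium), the **scope** of S
is the least fixed point of

    M₀ = S,    Mᵢ₊₁ = Mᵢ ∪ prod({ r ∈ R : reac(r) ⊆ Mᵢ })

A reaction fires only when *all* its reactants are producible; consequently a
cycle never self-starts — every one of its inputs must be produced
independently. Reversible reactions contribute one directed reaction per
direction.

Gap-filling: given a draft R_draft, a database R_database, seeds M_seed and
targets M_target, solve

    minimize |R_fill|   s.t.   R_fill ⊆ R_database,
                               M_target ∩ scope_{R_draft ∪ R_fill}(M_seed) maximal

Scope is monotone in the reaction set, so the maximal achievable target set
is unique (targets producible with the whole database added); minimization
then runs over that fixed set. The solver is **exact**: it returns the
optimum size, *all* cardinality-minimal completions, and their union and
intersection (brave/cautious consequences — the intersection flags reactions
indispensable to any parsimonious repair). Internally the semantics is
encoded as a mixed-integer program with acyclic-support level variables and
solved with HiGHS at zero MIP gap.

A separate LP layer validates filled networks stoichiometrically: flux
balance analysis (FBA) maximizes a biomass flux under S·v = 0 and bounds,
and flux variability analysis (FVA) over {S·v = 0, bounds, v_biomass ≥ δ}
classifies each reaction as **essential** (flux interval excludes 0),
**blocked** (interval is {0}) or **alternative** (anything else). A
degradation benchmark harness removes equal fractions of each class from a
reference network, gap-fills, and measures recovery of the removed essential
reactions.

## Worked example

The bundled worked example has one seed S, targets T1–T3, a four-reaction
draft containing an unseeded 3-metabolite cycle, and a database R1…R9:

```
$ topofill fixtures --kind fig1 --out .
$ topofill gapfill --draftnet fig1_draft.sbml --seeds fig1_seeds.txt \
      --targets fig1_targets.txt --repairnet fig1_database.sbml --enumerate
optimum size: 3
solution 1: R3 R4 R7
solution 2: R3 R6 R7
solution 3: R4 R5 R7
solution 4: R4 R7 R8
solution 5: R6 R7 R8
$ topofill gapfill ... --union
union (6): R3 R4 R5 R6 R7 R8
```

Three reactions suffice, in five interchangeable combinations. R7 appears in
every solution (it is the only producer of T1 and closes the draft cycle, so
the intersection is {R7}); R4 or R6 must seed the cycle from outside because
a cycle is never topologically self-starting; R9, which feeds the cycle only
from one of its own members, can never fire and is correctly left out.

The same API is available in Python:

```python
from topofill import enumerate_minimal_completions
from topofill.fixtures import fig1_instance

res = enumerate_minimal_completions(fig1_instance())
res.optimum_size        # 3
len(res.solutions)      # 5
sorted(res.union)       # ['R3', 'R4', 'R5', 'R6', 'R7', 'R8']
sorted(res.intersection)  # ['R7']
```

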