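"""Naive reference implementations used as independent oracles.

These deliberately use the slowest, most transparent formulation of each
question — sweep-to-convergence reachability, exhaustive subset search over
the database, and knock-out LPs — and exist to cross-check the production
solver on small instances.  They are exact but exponential/quadratic, so
keep databases below ~20 reactions.
"""

from __future__ import annotations

from itertools import combinations

from .flux import FluxModel, fba_max
from .network import CompletionResult, GapFillInstance, directed_view, merge_networks

__all__ = ["naive_scope", "brute_force_completions", "knockout_essential"]


def naive_scope(reactions, seeds) -> frozenset[str]:
    """Fixed point by full re-sweeps: keep scanning every reaction until no
    sweep adds a metabolite."""
    reactions = list(reactions)
    producible = set(seeds)
    changed = True
    while changed:
        changed = False
        for rxn in reactions:
            if rxn.reactants <= producible and not rxn.products <= producible:
                producible |= rxn.products
                changed = True
    return frozenset(producible)


def brute_force_completions(
    inst: GapFillInstance, max_database: int = 20
) -> CompletionResult:
    """Exhaustive subset search over database reactions, by increasing size.

    Selecting a reversible database reaction grants both of its directions at
    a cost of one, matching the production solver's convention.
    """
    candidates = sorted(inst.database_only_ids)
    if len(candidates) > max_database:
        raise ValueError(f"database too large for brute force: {len(candidates)}")

    draft_dirs = directed_view(inst.draft)
    db_dirs_by_parent = {}
    db_net = inst.database.remove_reactions(
        set(inst.database.reactions) - set(candidates)
    )
    for d in directed_view(db_net):
        db_dirs_by_parent.setdefault(d.origin_id, []).append(d)

    full = naive_scope(
        draft_dirs + [d for ds in db_dirs_by_parent.values() for d in ds], inst.seeds
    )
    reconstructable = frozenset(inst.targets & full)
    unreconstructable = frozenset(inst.targets - reconstructable)

    def works(subset) -> bool:
        dirs = list(draft_dirs)
        for rid in subset:
            dirs.extend(db_dirs_by_parent.get(rid, ()))
        return reconstructable <= naive_scope(dirs, inst.seeds)

    for k in range(len(candidates) + 1):
        solutions = [
            frozenset(subset)
            for subset in combinations(candidates, k)
            if works(subset)
        ]
        if solutions:
            solutions.sort(key=sorted)
            union = frozenset().union(*solutions)
            inter = solutions[0]
            for s in solutions[1:]:
                inter = inter & s
            return CompletionResult(
                reconstructable=reconstructable,
                unreconstructable=unreconstructable,
                optimum_size=k,
                solutions=solutions,
                union=union,
                intersection=frozenset(inter),
                enumeration_truncated=False,
            )
    raise AssertionError("unreachable: the full database is always feasible")


def knockout_essential(model: FluxModel, delta: float = 1.0) -> frozenset[str]:
    """Essential reactions by single knock-outs: r is essential iff pinning
    v_r = 0 drops the biomass optimum to <= delta."""
    essential = set()
    for rid in model.reaction_order:
        if rid == model.objective_id:
            essential.add(rid)
            continue
        ko = FluxModel(
            network=model.network,
            bounds={**model.bounds, rid: (0.0, 0.0)},
            objective_id=model.objective_id,
            exchange_ids=model.exchange_ids,
        )
        if not (fba_max(ko) > delta):
            essential.add(rid)
    return frozenset(essential)
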