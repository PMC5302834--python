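"""Forward-scope reachability: topological producibility.

The scope of a seed set S under a set of directed reactions is the least
fixed point of

    M_0 = S,   M_{i+1} = M_i  ∪  products of every reaction whose reactants
                              are all contained in M_i.

A reaction *fires* only once all of its reactants are producible; a
metabolite is producible iff it is a seed or the product of a fired reaction.
Cycles therefore do not self-start: every input of a cycle must be produced
independently before any cycle reaction can fire.  Stoichiometric
coefficients and boundary flags play no role here.

The implementation is queue-based: each directed reaction keeps a count of
not-yet-producible reactants and fires when the count hits zero, giving a
runtime linear in the total number of reactant/product arcs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .network import DirectedReaction, MetabolicNetwork, directed_view

__all__ = ["Scope", "compute_scope", "unproducible_targets"]


@dataclass(frozen=True)
class Scope:
    """Result of a scope computation.

    ``producible`` includes the seeds; ``fired`` holds every directed
    reaction whose reactants all ended up producible; ``iterations`` counts
    the breadth-first layers swept before the fixed point (0 when no reaction
    fires).
    """

    producible: frozenset[str]
    fired: frozenset[DirectedReaction]
    iterations: int


def compute_scope(reactions, seeds) -> Scope:
    """Least fixed point of the producibility relation.

    Total function: empty inputs are allowed, and the result is independent
    of the iteration order of ``reactions``.
    """
    reactions = list(reactions)
    producible: set[str] = set(seeds)
    fired: set[DirectedReaction] = set()

    missing = []  # per-reaction count of unsatisfied reactants
    waiting: dict[str, list[int]] = defaultdict(list)  # metabolite -> reaction idxs
    frontier: list[int] = []
    for idx, rxn in enumerate(reactions):
        unmet = sum(1 for m in rxn.reactants if m not in producible)
        missing.append(unmet)
        if unmet == 0:
            frontier.append(idx)  # fires unconditionally (incl. zero-reactant sources)
        else:
            for m in rxn.reactants:
                if m not in producible:
                    waiting[m].append(idx)

    iterations = 0
    while frontier:
        iterations += 1
        new_mets: set[str] = set()
        for idx in frontier:
            rxn = reactions[idx]
            if rxn in fired:
                continue
            fired.add(rxn)
            for m in rxn.products:
                if m not in producible:
                    producible.add(m)
                    new_mets.add(m)
        frontier = []
        for m in new_mets:
            for idx in waiting.get(m, ()):
                missing[idx] -= 1
                if missing[idx] == 0:
                    frontier.append(idx)

    return Scope(
        producible=frozenset(producible),
        fired=frozenset(fired),
        iterations=iterations,
    )


def unproducible_targets(net: MetabolicNetwork, seeds, targets) -> frozenset[str]:
    """Targets outside the scope of ``seeds`` in ``net``.

    An empty result means no gap-filling is needed.
    """
    scope = compute_scope(directed_view(net), seeds)
    return frozenset(targets) - scope.producible
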