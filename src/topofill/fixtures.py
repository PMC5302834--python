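"""Programmatic generators for worked-example networks and random instances
with planted ground truth.

Everything here is synthetic and built in memory, so the whole tool can be
exercised without downloading any repository model:

* :func:`fig1_instance` — a small draft + 9-reaction candidate database with
  three targets, whose minimal completions are known in closed form.
* :func:`fig2_network` — the producibility-semantics network exhibiting both
  directions of disagreement between topological scope and FBA (a
  stoichiometric branch ``S -> n a + b`` and a self-contained cycle
  ``j -> 2k -> l -> j``).
* :func:`planted_instance` — random chain instances with a planted optimal
  completion set (and all its interchangeable variants) known by
  construction.
* :func:`random_instance` — small unconstrained random instances for oracle
  comparison against brute-force subset search.
* :func:`benchmark_model` — a deterministic ~100-reaction FBA-functional
  network with a designed mix of essential, alternative and blocked
  reactions, used by the degradation benchmark.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np

from .network import GapFillInstance, MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "PlantedInstance",
    "fig1_instance",
    "fig2_network",
    "planted_instance",
    "random_instance",
    "benchmark_model",
    "canonical_form",
    "network_checksum",
]


@dataclass(frozen=True)
class PlantedInstance:
    """A gap-filling instance whose solver output is known by construction."""

    instance: GapFillInstance
    planted_optimum: int
    planted_solutions: tuple[frozenset[str], ...]
    forced_reactions: frozenset[str]


def _net(reactions: dict[str, tuple[dict, dict]], reversible=()) -> MetabolicNetwork:
    net = MetabolicNetwork()
    for rid, (reac, prod) in reactions.items():
        net.add_reaction(
            Reaction(id=rid, reactants=reac, products=prod, reversible=rid in reversible)
        )
    return net


def fig1_instance() -> GapFillInstance:
    """Toy worked example: draft with a 3-metabolite cycle, one seed S and
    targets T1, T2, T3; database reactions R1..R9.

    Ground truth (all irreversible, coefficients 1): the optimum completion
    size is 3 and the five minimal completions are {R3,R4,R7}, {R3,R6,R7},
    {R4,R5,R7}, {R6,R7,R8}, {R4,R7,R8} — union of six reactions R3..R8,
    intersection {R7}.  R7 closes the cycle and is the only producer of T1,
    so it is indispensable; R4 or R6 must seed the cycle from outside
    (topologically a cycle never self-starts); R9 feeds the cycle from a
    cycle metabolite and therefore can never fire; the two-reaction route
    R1,R2 to T2 loses to the one-reaction alternatives R3/R5/R8.
    """
    draft = _net(
        {
            "D1": ({"c1": 1.0}, {"c2": 1.0}),
            "D2": ({"c2": 1.0}, {"c3": 1.0}),
            "D3": ({"m4": 1.0}, {"c1": 1.0}),
            "D4": ({"c3": 1.0}, {"T3": 1.0}),
        }
    )
    database = _net(
        {
            "R1": ({"S": 1.0}, {"p1": 1.0}),
            "R2": ({"p1": 1.0}, {"T2": 1.0}),
            "R3": ({"S": 1.0}, {"T2": 1.0}),
            "R4": ({"S": 1.0}, {"m4": 1.0}),
            "R5": ({"m4": 1.0}, {"T2": 1.0}),
            "R6": ({"S": 1.0}, {"c2": 1.0}),
            "R7": ({"c3": 1.0}, {"c1": 1.0, "T1": 1.0}),
            "R8": ({"T1": 1.0}, {"T2": 1.0}),
            "R9": ({"c3": 1.0}, {"c2": 1.0}),
        }
    )
    return GapFillInstance(
        draft=draft,
        database=database,
        seeds=frozenset({"S"}),
        targets=frozenset({"T1", "T2", "T3"}),
    )


FIG1_SOLUTIONS = (
    frozenset({"R3", "R4", "R7"}),
    frozenset({"R3", "R6", "R7"}),
    frozenset({"R4", "R5", "R7"}),
    frozenset({"R4", "R7", "R8"}),
    frozenset({"R6", "R7", "R8"}),
)


def fig2_network(n: float = 2.0):
    """Producibility-semantics network; returns (network, seeds).

    From seed S every metabolite on the branch side is topologically
    producible, but stoichiometry disagrees twice:

    * ``src: S -> n a + b`` feeds ``a + b -> d`` and ``a -> c``; T1 needs c
      and d in equal amounts, so T1 is FBA-producible only for n = 2 while
      the scope criterion accepts any n.
    * ``split: T1 -> e + f`` strands f (no consumer), so T2 is always
      FBA-blocked yet topologically producible.
    * the cycle ``j -> 2k, k -> l, l -> j`` makes k FBA-producible (the loop
      can carry flux and nets one k per turn) although no topological route
      from S reaches j, k or l.
    * T3 and T4 (side branch through g) are producible by both criteria.
    """
    net = _net(
        {
            "src": ({"S": 1.0}, {"a": float(n), "b": 1.0}),
            "to_d": ({"a": 1.0, "b": 1.0}, {"d": 1.0}),
            "to_c": ({"a": 1.0}, {"c": 1.0}),
            "to_T1": ({"c": 1.0, "d": 1.0}, {"T1": 1.0}),
            "split": ({"T1": 1.0}, {"e": 1.0, "f": 1.0}),
            "to_T2": ({"e": 1.0}, {"T2": 1.0}),
            "branch": ({"S": 1.0}, {"g": 1.0}),
            "to_T3": ({"g": 1.0}, {"T3": 1.0}),
            "to_T4": ({"g": 1.0}, {"T4": 1.0}),
            "cyc_j": ({"j": 1.0}, {"k": 2.0}),
            "cyc_k": ({"k": 1.0}, {"l": 1.0}),
            "cyc_l": ({"l": 1.0}, {"j": 1.0}),
        }
    )
    return net, frozenset({"S"})


def planted_instance(
    n_layers: int, width: int, n_distractors: int, rng_seed: int
) -> PlantedInstance:
    """Chain instance with a planted set of minimal completions.

    A single chain S -> m1 -> ... -> T of ``n_layers`` reactions is built; a
    random subset of 1..min(3, n_layers) chain reactions is moved into the
    database (the planted cut — crossed by every seed-to-target route), each
    with 1..``width`` interchangeable database variants.  Minimal completions
    are exactly one variant per cut position; positions with a single variant
    are forced into every solution.  Distractors alternate between
    never-firable reactions (consuming a fresh unproducible metabolite) and
    redundant duplicates of surviving draft reactions.
    """
    if n_layers < 1 or width < 1:
        raise ValueError("n_layers and width must be positive")
    rng = np.random.default_rng(rng_seed)
    mets = ["S"] + [f"m{i}" for i in range(1, n_layers)] + ["T"]

    k = int(rng.integers(1, min(3, n_layers) + 1))
    cut = sorted(int(i) for i in rng.choice(n_layers, size=k, replace=False))

    draft = MetabolicNetwork()
    database = MetabolicNetwork()
    variants: list[list[str]] = []
    for i in range(n_layers):
        reac, prod = {mets[i]: 1.0}, {mets[i + 1]: 1.0}
        if i in cut:
            n_var = int(rng.integers(1, width + 1))
            ids = [f"fill_{i}"] + [f"fill_{i}_alt{j}" for j in range(1, n_var)]
            for rid in ids:
                database.add_reaction(Reaction(id=rid, reactants=reac, products=prod))
            variants.append(ids)
        else:
            draft.add_reaction(Reaction(id=f"chain_{i}", reactants=reac, products=prod))

    non_cut = [i for i in range(n_layers) if i not in cut]
    for t in range(n_distractors):
        if t % 2 == 0 or not non_cut:
            database.add_reaction(
                Reaction(
                    id=f"junk_{t}",
                    reactants={f"u{t}": 1.0},
                    products={f"x{t}": 1.0},
                )
            )
        else:
            i = non_cut[int(rng.integers(len(non_cut)))]
            database.add_reaction(
                Reaction(
                    id=f"dup_{t}",
                    reactants={mets[i]: 1.0},
                    products={mets[i + 1]: 1.0},
                )
            )

    solutions = tuple(
        sorted(
            (frozenset(combo) for combo in itertools.product(*variants)),
            key=sorted,
        )
    )
    forced = frozenset(ids[0] for ids in variants if len(ids) == 1)
    inst = GapFillInstance(
        draft=draft,
        database=database,
        seeds=frozenset({"S"}),
        targets=frozenset({"T"}),
    )
    return PlantedInstance(
        instance=inst,
        planted_optimum=k,
        planted_solutions=solutions,
        forced_reactions=forced,
    )


def random_instance(
    rng_seed: int,
    n_metabolites: int = 10,
    n_draft: int = 5,
    n_database: int = 8,
    p_reversible: float = 0.15,
) -> GapFillInstance:
    """Small random instance for oracle comparison (no planted truth;
    targets may or may not be reconstructable)."""
    rng = np.random.default_rng(rng_seed)
    mets = [f"M{i}" for i in range(n_metabolites)]

    def rand_reaction(rid):
        n_reac = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(n_metabolites, size=n_reac + n_prod, replace=False)
        return Reaction(
            id=rid,
            reactants={mets[i]: 1.0 for i in picks[:n_reac]},
            products={mets[i]: 1.0 for i in picks[n_reac:]},
            reversible=bool(rng.random() < p_reversible),
        )

    draft = MetabolicNetwork(metabolites=[Metabolite(m) for m in mets])
    database = MetabolicNetwork(metabolites=[Metabolite(m) for m in mets])
    for i in range(n_draft):
        draft.add_reaction(rand_reaction(f"D{i}"))
    for i in range(n_database):
        database.add_reaction(rand_reaction(f"B{i}"))
    seeds = frozenset(mets[:2])
    targets = frozenset(
        mets[i] for i in rng.choice(np.arange(2, n_metabolites), size=2, replace=False)
    )
    return GapFillInstance(draft=draft, database=database, seeds=seeds, targets=targets)


def benchmark_model(
    n_modules: int = 5,
    chain_len: int = 8,
    branch_len: int = 3,
    n_blocked: int = 6,
):
    """Deterministic benchmark network; returns (network, seeds, biomass_id).

    Each module converts a seed nutrient through a linear trunk chain
    (essential: the only route to that precursor), then through two parallel
    branches (alternative: either can carry the flux) into a biomass
    precursor, and carries dead-end appendages that can never sustain
    steady-state flux (blocked).  The biomass reaction consumes one precursor
    per module.  Defaults give 101 reactions (40 essential chain steps + the
    biomass, 30 alternative, 30 blocked) and an FBA-functional model on the
    two seed nutrients.
    """
    net = MetabolicNetwork()
    seeds = frozenset({"N1", "N2"})
    for s in sorted(seeds):
        net.add_metabolite(Metabolite(s))
    precursors = []
    for mod in range(1, n_modules + 1):
        src = "N1" if mod % 2 else "N2"
        prev = src
        for j in range(1, chain_len + 1):
            cur = f"t{mod}_{j}"
            net.add_reaction(
                Reaction(id=f"chain{mod}_{j}", reactants={prev: 1.0}, products={cur: 1.0})
            )
            prev = cur
        hub = prev
        prec = f"P{mod}"
        for branch in ("a", "b"):
            bprev = hub
            for j in range(1, branch_len + 1):
                cur = prec if j == branch_len else f"{branch}{mod}_{j}"
                net.add_reaction(
                    Reaction(
                        id=f"alt{mod}_{branch}{j}",
                        reactants={bprev: 1.0},
                        products={cur: 1.0},
                    )
                )
                bprev = cur
        # blocked appendages: half consume the hub into dead ends, half sit
        # behind a metabolite nothing produces
        for j in range(1, n_blocked + 1):
            if j <= n_blocked // 2:
                net.add_reaction(
                    Reaction(
                        id=f"dead{mod}_{j}",
                        reactants={hub: 1.0},
                        products={f"w{mod}_{j}": 1.0},
                    )
                )
            else:
                net.add_reaction(
                    Reaction(
                        id=f"orphan{mod}_{j}",
                        reactants={f"u{mod}_{j}": 1.0},
                        products={f"w{mod}_{j}": 1.0},
                    )
                )
        precursors.append(prec)
    net.add_reaction(
        Reaction(id="BIOMASS", reactants={p: 1.0 for p in precursors})
    )
    return net, seeds, "BIOMASS"


# ---------------------------------------------------------------------------
# Golden-fixture freezing
# ---------------------------------------------------------------------------

def canonical_form(net: MetabolicNetwork) -> str:
    """Byte-stable text rendering of a network's content (used to freeze the
    worked-example fixtures against accidental edits)."""
    lines = []
    for mid in sorted(net.metabolites):
        m = net.metabolites[mid]
        lines.append(f"M\t{m.id}\t{int(m.boundary)}")
    for rid in sorted(net.reactions):
        r = net.reactions[rid]
        reac = ",".join(f"{m}:{r.reactants[m]:g}" for m in sorted(r.reactants))
        prod = ",".join(f"{m}:{r.products[m]:g}" for m in sorted(r.products))
        lines.append(f"R\t{r.id}\t{int(r.reversible)}\t{reac}\t{prod}")
    return "\n".join(lines) + "\n"


def network_checksum(net: MetabolicNetwork) -> str:
    return hashlib.sha256(canonical_form(net).encode()).hexdigest()
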