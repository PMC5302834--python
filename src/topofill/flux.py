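"""LP-based validation of (filled) networks.

Flux balance analysis (FBA) maximises the flux of a named objective reaction
subject to steady-state mass balance S·v = 0 over the non-boundary
metabolites and per-reaction flux bounds (reversible [-1000, 1000],
irreversible [0, 1000] by default).  Seed metabolites get one import
exchange reaction each, mirroring growth-medium uptake.

Flux variability analysis (FVA) over the region with a biomass floor
(v_biomass >= delta) classifies every reaction as

* blocked      — the flux is always 0,
* essential    — the flux interval excludes 0,
* alternative  — the flux may be 0 or not.

This is the stoichiometric counterpart of topological producibility: the two
disagree in both directions (stoichiometric coefficients can block a
topologically producible compound; an internal cycle can carry FBA flux into
a compound no topological route reaches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import NonFunctionalModelError, TopofillError
from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "FluxModel",
    "FBAResult",
    "ReactionClass",
    "build_flux_model",
    "fba_max",
    "classify_reactions",
    "add_demand",
    "DEFAULT_BOUND",
    "LP_TOL",
]

DEFAULT_BOUND = 1000.0
LP_TOL = 1e-6


@dataclass
class FluxModel:
    """A stoichiometric model ready for LP: network (including the seed
    exchanges), per-reaction bounds, and the objective reaction id."""

    network: MetabolicNetwork
    bounds: dict[str, tuple[float, float]]
    objective_id: str
    exchange_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.objective_id not in self.network.reactions:
            raise TopofillError(
                f"objective reaction {self.objective_id!r} not in network"
            )
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise TopofillError(f"reaction {rid!r}: lower bound > upper bound")

    # column order is fixed and deterministic
    @property
    def reaction_order(self) -> list[str]:
        return sorted(self.network.reactions)

    def stoichiometric_matrix(self):
        """(rows, S): balanced metabolite ids (non-boundary, sorted) and the
        dense stoichiometric matrix with columns in ``reaction_order``."""
        rows = sorted(
            m.id for m in self.network.metabolites.values() if not m.boundary
        )
        ridx = {m: i for i, m in enumerate(rows)}
        order = self.reaction_order
        S = np.zeros((len(rows), len(order)))
        for j, rid in enumerate(order):
            rxn = self.network.reactions[rid]
            for mid, coeff in rxn.reactants.items():
                if mid in ridx:
                    S[ridx[mid], j] -= coeff
            for mid, coeff in rxn.products.items():
                if mid in ridx:
                    S[ridx[mid], j] += coeff
        return rows, S

    def bounds_arrays(self, extra: dict[str, tuple[float, float]] | None = None):
        order = self.reaction_order
        lo = np.empty(len(order))
        hi = np.empty(len(order))
        for j, rid in enumerate(order):
            lo[j], hi[j] = self.bounds[rid]
            if extra and rid in extra:
                elo, ehi = extra[rid]
                lo[j], hi[j] = max(lo[j], elo), min(hi[j], ehi)
        return lo, hi


class FBAResult(float):
    """Maximum objective flux; ``infeasible`` flags an LP with no feasible
    steady state (value reported as 0)."""

    def __new__(cls, value: float, infeasible: bool = False):
        obj = super().__new__(cls, value)
        obj.infeasible = infeasible
        return obj

    @property
    def value(self) -> float:
        return float(self)


@dataclass
class ReactionClass:
    """Partition of reactions into essential/alternative/blocked relative to
    a biomass objective, with the FVA intervals that justified it."""

    labels: dict[str, str]
    intervals: dict[str, tuple[float, float]]
    objective_id: str
    delta: float

    def of_class(self, label: str) -> frozenset[str]:
        return frozenset(r for r, c in self.labels.items() if c == label)

    @property
    def essential(self) -> frozenset[str]:
        return self.of_class("essential")

    @property
    def alternative(self) -> frozenset[str]:
        return self.of_class("alternative")

    @property
    def blocked(self) -> frozenset[str]:
        return self.of_class("blocked")


def build_flux_model(
    net: MetabolicNetwork,
    seeds,
    objective_id: str,
    default_bound: float = DEFAULT_BOUND,
) -> FluxModel:
    """Copy ``net``, add one import exchange per seed (bounds [0, bound]) and
    apply default bounds (reversible ±bound, irreversible [0, bound])."""
    if objective_id not in net.reactions:
        raise TopofillError(f"objective reaction {objective_id!r} not in network")
    model_net = net.copy()
    exchange_ids = set()
    bounds: dict[str, tuple[float, float]] = {}
    for rid, rxn in model_net.reactions.items():
        bounds[rid] = (-default_bound if rxn.reversible else 0.0, default_bound)
    for seed in sorted(seeds):
        if seed not in model_net.metabolites:
            model_net.add_metabolite(Metabolite(seed))
        ex_id = f"EX_{seed}"
        if ex_id in model_net.reactions:
            raise TopofillError(f"exchange id {ex_id!r} collides with a reaction")
        model_net.add_reaction(Reaction(id=ex_id, products={seed: 1.0}))
        exchange_ids.add(ex_id)
        bounds[ex_id] = (0.0, default_bound)
    return FluxModel(
        network=model_net,
        bounds=bounds,
        objective_id=objective_id,
        exchange_ids=frozenset(exchange_ids),
    )


def add_demand(net: MetabolicNetwork, metabolite_ids, demand_id: str) -> MetabolicNetwork:
    """Convenience: copy of ``net`` with an irreversible reaction consuming
    the given metabolites (a demand/objective reaction)."""
    out = net.copy()
    out.add_reaction(
        Reaction(id=demand_id, reactants={m: 1.0 for m in metabolite_ids})
    )
    return out


def _lp(model: FluxModel, c, extra_bounds=None):
    _, S = model.stoichiometric_matrix()
    lo, hi = model.bounds_arrays(extra_bounds)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    return res


def fba_max(model: FluxModel) -> FBAResult:
    """Maximum objective flux; infeasible LPs report 0 with a flag set."""
    order = model.reaction_order
    c = np.zeros(len(order))
    c[order.index(model.objective_id)] = -1.0
    res = _lp(model, c)
    if res.status == 2:
        return FBAResult(0.0, infeasible=True)
    if res.status != 0:
        raise TopofillError(f"FBA LP failed: {res.message}")
    return FBAResult(-res.fun)


def classify_reactions(
    model: FluxModel, delta: float = 1.0, tol: float = LP_TOL
) -> ReactionClass:
    """FVA classification over {S·v = 0, bounds, v_objective >= delta}.

    Requires ``fba_max(model) > delta``; blocked means both FVA extrema are 0
    within ``tol``, essential means the interval excludes 0 beyond ``tol``.
    """
    opt = fba_max(model)
    if not (opt > delta):
        raise NonFunctionalModelError(
            f"objective optimum {float(opt):.6g} does not exceed the biomass "
            f"floor delta={delta}; run fba_max and check functionality first"
        )
    floor = {model.objective_id: (delta, np.inf)}
    order = model.reaction_order
    labels: dict[str, str] = {}
    intervals: dict[str, tuple[float, float]] = {}
    for j, rid in enumerate(order):
        c = np.zeros(len(order))
        c[j] = 1.0
        lo_res = _lp(model, c, extra_bounds=floor)
        c[j] = -1.0
        hi_res = _lp(model, c, extra_bounds=floor)
        if lo_res.status != 0 or hi_res.status != 0:
            raise TopofillError(f"FVA LP failed for reaction {rid!r}")
        lo, hi = lo_res.fun, -hi_res.fun
        intervals[rid] = (lo, hi)
        if abs(lo) <= tol and abs(hi) <= tol:
            labels[rid] = "blocked"
        elif lo > tol or hi < -tol:
            labels[rid] = "essential"
        else:
            labels[rid] = "alternative"
    return ReactionClass(
        labels=labels, intervals=intervals, objective_id=model.objective_id, delta=delta
    )
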