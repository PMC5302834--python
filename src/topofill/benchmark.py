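"""Degradation benchmark harness.

Experimental design, at configurable scale: draw a random biomass variant
(Bernoulli zeroing of precursor coefficients), classify every reaction as
essential / alternative / blocked with respect to that biomass, remove the
same fraction of reactions from each class (stratified degradation,
optionally resampled until the degraded model cannot produce biomass),
gap-fill topologically against a reference database, and evaluate the filled
network: FBA functionality, recovery of the removed essential reactions, and
classification drift between the reference and filled networks.

One theorem anchors the evaluation: a network restored to FBA functionality
necessarily contains every reference-essential reaction, because an
essential reaction by definition carries non-zero flux whenever biomass is
produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .completion import SolverOptions, union_of_minimal
from .errors import TopofillError
from .flux import LP_TOL, ReactionClass, build_flux_model, classify_reactions, fba_max
from .network import GapFillInstance, MetabolicNetwork, Reaction

__all__ = [
    "DegradationRecord",
    "EvaluationReport",
    "random_biomass",
    "degrade",
    "evaluate",
    "run_benchmark",
    "CLASS_ORDER",
]

CLASS_ORDER = ("essential", "alternative", "blocked")


@dataclass
class DegradationRecord:
    """Bookkeeping for one stratified degradation."""

    reference: MetabolicNetwork
    degraded: MetabolicNetwork
    removed: frozenset[str]
    per_class_removed: dict[str, int]
    rng_seed: int
    fraction: float
    seeds: frozenset[str] = frozenset()
    biomass_id: str | None = None


@dataclass
class EvaluationReport:
    """Outcome of one degrade/fill/evaluate experiment.

    ``category`` follows the four-way grading of completions: (i) biomass
    production restored; (ii) all removed essential reactions recovered but
    not functional; (iii) exactly one essential reaction missed; (iv) more
    than one missed.
    """

    functional_after: bool
    essential_removed: int
    essential_recovered: int
    missed_essential: int
    recovery_fraction: float
    solution_size: int
    category: str
    class_drift: dict[str, dict[str, int]] | None = None

    @property
    def all_essential_recovered(self) -> bool:
        return self.missed_essential == 0


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def random_biomass(
    net: MetabolicNetwork, base_biomass: str, zero_prob: float, rng_seed: int
) -> Reaction:
    """Random biomass variant: each reactant coefficient is independently
    zeroed (dropped) with probability ``zero_prob``; resampled if all
    reactants would vanish.  Deterministic given ``rng_seed``."""
    if base_biomass not in net.reactions:
        raise TopofillError(f"biomass reaction {base_biomass!r} not in network")
    base = net.reactions[base_biomass]
    if not base.reactants:
        raise TopofillError(f"biomass reaction {base_biomass!r} has no reactants")
    if not (0 <= zero_prob < 1):
        raise ValueError("zero_prob must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    order = sorted(base.reactants)
    while True:
        keep = {m: base.reactants[m] for m in order if rng.random() >= zero_prob}
        if keep:
            break
    return Reaction(
        id=base.id,
        reactants=keep,
        products=dict(base.products),
        reversible=base.reversible,
        name=base.name,
    )


def _stratified_counts(class_sizes: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-class removal counts: round half away from zero per class, then
    adjust the largest class by +-1 so the global count matches
    round(fraction * total)."""
    total = sum(class_sizes.values())
    target_total = _round_half_away(fraction * total)
    counts = {c: min(_round_half_away(fraction * n), n) for c, n in class_sizes.items()}
    largest = max(class_sizes, key=lambda c: (class_sizes[c], c))
    diff = target_total - sum(counts.values())
    counts[largest] = int(np.clip(counts[largest] + diff, 0, class_sizes[largest]))
    return counts


def degrade(
    net: MetabolicNetwork,
    fraction: float,
    classes: ReactionClass,
    rng_seed: int,
    biomass_id: str,
    require_nonfunctional: bool = False,
    seeds=frozenset(),
    max_retries: int = 100,
) -> DegradationRecord:
    """Remove the same fraction of essential, alternative and blocked
    reactions, sampled uniformly without replacement within each class.

    The biomass reaction itself is never removed.  With
    ``require_nonfunctional`` the sampling is repeated (bounded retries,
    fresh deterministic substreams) until the degraded model's biomass
    optimum is ~0.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    # classification may cover model-only reactions (seed exchanges); only
    # reactions of the network proper are eligible for removal
    pools = {
        c: sorted(
            r for r in classes.of_class(c) if r != biomass_id and r in net.reactions
        )
        for c in CLASS_ORDER
    }
    counts = _stratified_counts({c: len(p) for c, p in pools.items()}, fraction)

    for attempt in range(max_retries):
        rng = np.random.default_rng([rng_seed, attempt])
        removed: set[str] = set()
        for c in CLASS_ORDER:
            if counts[c]:
                removed |= {
                    pools[c][i]
                    for i in rng.choice(len(pools[c]), size=counts[c], replace=False)
                }
        degraded = net.remove_reactions(removed)
        if require_nonfunctional:
            opt = fba_max(build_flux_model(degraded, seeds, biomass_id))
            if opt > LP_TOL:
                continue
        return DegradationRecord(
            reference=net,
            degraded=degraded,
            removed=frozenset(removed),
            per_class_removed=counts,
            rng_seed=rng_seed,
            fraction=fraction,
            seeds=frozenset(seeds),
            biomass_id=biomass_id,
        )
    raise TopofillError(
        f"could not reach a non-functional degradation in {max_retries} attempts"
    )


def evaluate(
    record: DegradationRecord,
    filled: MetabolicNetwork,
    biomass_id: str,
    delta: float = 1.0,
    reference_classes: ReactionClass | None = None,
) -> EvaluationReport:
    """Score a filled network against its degradation record.

    Essential recovery counts removed reactions that were essential in the
    reference (w.r.t. this biomass) and reappear in ``filled``; class drift
    compares the FVA classification of reference vs filled reactions when
    both models are functional.
    """
    if biomass_id not in filled.reactions:
        raise TopofillError(f"biomass reaction {biomass_id!r} absent from filled network")
    missing = set(record.degraded.reactions) - set(filled.reactions)
    if missing:
        raise TopofillError(
            f"filled network lost degraded reactions: {sorted(missing)[:5]}"
        )
    seeds = record.seeds
    if reference_classes is None:
        reference_classes = classify_reactions(
            build_flux_model(record.reference, seeds, biomass_id), delta=delta
        )
    removed_essential = sorted(record.removed & reference_classes.essential)
    recovered = [r for r in removed_essential if r in filled.reactions]
    missed = len(removed_essential) - len(recovered)

    filled_opt = fba_max(build_flux_model(filled, seeds, biomass_id))
    functional = bool(filled_opt > delta and not filled_opt.infeasible)

    drift = None
    if functional:
        filled_classes = classify_reactions(
            build_flux_model(filled, seeds, biomass_id), delta=delta
        )
        drift = {c: {c2: 0 for c2 in CLASS_ORDER} for c in CLASS_ORDER}
        for rid in filled.reactions:
            ref_c = reference_classes.labels.get(rid)
            fil_c = filled_classes.labels.get(rid)
            if ref_c in drift and fil_c in CLASS_ORDER:
                drift[ref_c][fil_c] += 1

    if functional:
        category = "i"
    elif missed == 0:
        category = "ii"
    elif missed == 1:
        category = "iii"
    else:
        category = "iv"

    return EvaluationReport(
        functional_after=functional,
        essential_removed=len(removed_essential),
        essential_recovered=len(recovered),
        missed_essential=missed,
        recovery_fraction=(
            1.0 if not removed_essential else len(recovered) / len(removed_essential)
        ),
        solution_size=len(filled.reactions) - len(record.degraded.reactions),
        category=category,
        class_drift=drift,
    )


def run_benchmark(
    net: MetabolicNetwork,
    seeds,
    biomass_id: str,
    fractions=(0.1, 0.2, 0.3, 0.4),
    rng_seeds=(0, 1, 2),
    zero_prob: float = 0.3,
    delta: float = 1.0,
    require_nonfunctional: bool = True,
    solver_options: SolverOptions | None = None,
):
    """Full degrade/fill/evaluate grid; yields one row dict per experiment.

    Per (fraction, seed): draw a random biomass, classify the reference with
    respect to it, degrade stratified by class, gap-fill the degraded network
    against the intact reference as database, fill with the union of all
    minimal completions, evaluate.
    """
    rows = []
    for rep in rng_seeds:
        biomass = random_biomass(net, biomass_id, zero_prob, rng_seed=rep)
        reference = net.remove_reactions([biomass_id])
        reference.add_reaction(biomass)
        ref_classes = classify_reactions(
            build_flux_model(reference, seeds, biomass_id), delta=delta
        )
        for fraction in fractions:
            record = degrade(
                reference,
                fraction,
                ref_classes,
                rng_seed=rep,
                biomass_id=biomass_id,
                require_nonfunctional=require_nonfunctional,
                seeds=seeds,
            )
            targets = frozenset(biomass.reactants) - frozenset(seeds)
            inst = GapFillInstance(
                draft=record.degraded,
                database=reference,
                seeds=frozenset(seeds),
                targets=targets,
            )
            fill = union_of_minimal(inst, solver_options)
            filled = record.degraded.copy()
            for rid in sorted(fill):
                filled.add_reaction(reference.reactions[rid])
            report = evaluate(
                record, filled, biomass_id, delta=delta, reference_classes=ref_classes
            )
            rows.append(
                {
                    "fraction": fraction,
                    "rng_seed": rep,
                    "n_removed": len(record.removed),
                    "per_class_removed": dict(record.per_class_removed),
                    "per_class_total": {
                        c: len(
                            [
                                r
                                for r in ref_classes.of_class(c)
                                if r != biomass_id and r in reference.reactions
                            ]
                        )
                        for c in CLASS_ORDER
                    },
                    "solution_size": report.solution_size,
                    "functional_after": report.functional_after,
                    "essential_removed": report.essential_removed,
                    "essential_recovered": report.essential_recovered,
                    "missed_essential": report.missed_essential,
                    "recovery_fraction": report.recovery_fraction,
                    "category": report.category,
                }
            )
    return rows
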