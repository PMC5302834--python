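"""Domain types for metabolic networks plus SBML / id-list readers and writers.

A metabolic network is a bipartite directed graph over reactions and
metabolites.  Reactions carry positive stoichiometric coefficients on both
sides and a reversibility flag; for purely topological computations a network
is expanded into *directed* reactions (one per irreversible reaction, two per
reversible one) with coefficients dropped.

SBML Level 2 (v4+) and Level 3 documents are supported through python-libsbml.
Seeds and targets may also be given as plain-text files with one metabolite id
per line ('#' comments and blank lines ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import libsbml

from .errors import MergeConflictError, NetworkParseError, NetworkValidationError

__all__ = [
    "Metabolite",
    "Reaction",
    "DirectedReaction",
    "MetabolicNetwork",
    "GapFillInstance",
    "CompletionResult",
    "read_network",
    "write_network",
    "merge_networks",
    "directed_view",
]


@dataclass(frozen=True)
class Metabolite:
    """A metabolite node.

    ``boundary`` marks SBML boundary-condition species: they are excluded
    from steady-state mass balance during flux validation but play no role in
    topological producibility.
    """

    id: str
    name: str | None = None
    boundary: bool = False

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A reaction with positive stoichiometric coefficients on each side.

    A metabolite may appear both as reactant and product (distinct entries).
    At least one of the two sides must be non-empty.
    """

    id: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    name: str | None = None

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        if not self.reactants and not self.products:
            raise NetworkValidationError(
                f"reaction {self.id!r}: both sides empty"
            )
        for side, coeffs in (("reactant", self.reactants), ("product", self.products)):
            for mid, coeff in coeffs.items():
                if not (coeff > 0) or not math.isfinite(coeff):
                    raise NetworkValidationError(
                        f"reaction {self.id!r}: {side} {mid!r} has "
                        f"non-positive coefficient {coeff!r}"
                    )

    def same_content(self, other: "Reaction") -> bool:
        """Structural equality ignoring the display name."""
        return (
            self.id == other.id
            and self.reversible == other.reversible
            and self.reactants == other.reactants
            and self.products == other.products
        )


@dataclass(frozen=True)
class DirectedReaction:
    """One firing direction of a reaction; coefficients are dropped.

    ``backward`` directions exist only for reversible parents and have the
    reactant/product sets swapped.
    """

    origin_id: str
    direction: str  # "forward" | "backward"
    reactants: frozenset[str]
    products: frozenset[str]

    @property
    def key(self) -> tuple[str, str]:
        return (self.origin_id, self.direction)


class MetabolicNetwork:
    """Id-keyed collections of metabolites and reactions.

    Every metabolite id referenced by a reaction is guaranteed to exist in
    ``metabolites``: :meth:`add_reaction` registers missing ones (as plain,
    non-boundary metabolites) unless told otherwise.
    """

    def __init__(self, metabolites=(), reactions=()):
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    def add_metabolite(self, met: Metabolite) -> None:
        existing = self.metabolites.get(met.id)
        if existing is not None and existing != met:
            raise NetworkValidationError(
                f"metabolite id {met.id!r} already defined differently"
            )
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, create_missing: bool = True) -> None:
        if rxn.id in self.reactions and not self.reactions[rxn.id].same_content(rxn):
            raise NetworkValidationError(
                f"reaction id {rxn.id!r} already defined differently"
            )
        for mid in (*rxn.reactants, *rxn.products):
            if mid not in self.metabolites:
                if not create_missing:
                    raise NetworkValidationError(
                        f"reaction {rxn.id!r} references undeclared "
                        f"metabolite {mid!r}"
                    )
                self.metabolites[mid] = Metabolite(mid)
        self.reactions[rxn.id] = rxn

    def remove_reactions(self, reaction_ids) -> "MetabolicNetwork":
        """New network without the given reactions (metabolites kept)."""
        drop = set(reaction_ids)
        out = MetabolicNetwork()
        for m in self.metabolites.values():
            out.add_metabolite(m)
        for r in self.reactions.values():
            if r.id not in drop:
                out.add_reaction(r)
        return out

    def copy(self) -> "MetabolicNetwork":
        return self.remove_reactions(())

    def content_equal(self, other: "MetabolicNetwork") -> bool:
        return (
            self.metabolites == other.metabolites
            and set(self.reactions) == set(other.reactions)
            and all(
                self.reactions[rid].same_content(other.reactions[rid])
                for rid in self.reactions
            )
        )

    def __repr__(self):
        return (
            f"<MetabolicNetwork {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


@dataclass
class GapFillInstance:
    """A gap-filling problem: draft network, candidate database, seeds, targets.

    Seeds and targets may reference metabolites absent from draft and
    database; such a target is simply unreconstructable.  A reaction id
    shared between draft and database must denote the identical reaction
    (the database copy is then redundant and silently deduplicated by the
    solver).
    """

    draft: MetabolicNetwork
    database: MetabolicNetwork
    seeds: frozenset[str]
    targets: frozenset[str]

    def __post_init__(self):
        self.seeds = frozenset(self.seeds)
        self.targets = frozenset(self.targets)
        if not self.seeds:
            raise NetworkValidationError("seed set must be non-empty")
        if not self.targets:
            raise NetworkValidationError("target set must be non-empty")
        clashes = [
            rid
            for rid in set(self.draft.reactions) & set(self.database.reactions)
            if not self.draft.reactions[rid].same_content(self.database.reactions[rid])
        ]
        if clashes:
            raise MergeConflictError(clashes)

    @property
    def database_only_ids(self) -> frozenset[str]:
        """Database reactions not already present in the draft."""
        return frozenset(set(self.database.reactions) - set(self.draft.reactions))


@dataclass
class CompletionResult:
    """Output of exhaustive cardinality-minimal completion enumeration."""

    reconstructable: frozenset[str]
    unreconstructable: frozenset[str]
    optimum_size: int
    solutions: list[frozenset[str]]
    union: frozenset[str]
    intersection: frozenset[str]
    enumeration_truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "reconstructable": sorted(self.reconstructable),
            "unreconstructable": sorted(self.unreconstructable),
            "optimum_size": self.optimum_size,
            "solutions": [sorted(s) for s in self.solutions],
            "union": sorted(self.union),
            "intersection": sorted(self.intersection),
            "enumeration_truncated": self.enumeration_truncated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompletionResult":
        return cls(
            reconstructable=frozenset(d["reconstructable"]),
            unreconstructable=frozenset(d["unreconstructable"]),
            optimum_size=int(d["optimum_size"]),
            solutions=[frozenset(s) for s in d["solutions"]],
            union=frozenset(d["union"]),
            intersection=frozenset(d["intersection"]),
            enumeration_truncated=bool(d["enumeration_truncated"]),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_dialect(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".txt", ".lst", ".ids", ".tsv")):
        return "idlist"
    return "sbml"


def read_network(path, dialect: str | None = None) -> MetabolicNetwork:
    """Read a network from ``path``.

    ``dialect`` is ``"sbml"`` or ``"idlist"``; when None it is inferred from
    the file extension (plain-text extensions map to idlist).  The idlist
    dialect yields a network of isolated metabolites and no reactions, as
    used for seed and target files.
    """
    if dialect is None:
        dialect = _detect_dialect(path)
    if dialect == "idlist":
        return _read_idlist(path)
    if dialect == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_idlist(path) -> MetabolicNetwork:
    net = MetabolicNetwork()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if any(ch.isspace() for ch in line):
                raise NetworkParseError(
                    f"{path}:{lineno}: expected one id per line, got {line!r}"
                )
            net.add_metabolite(Metabolite(line))
    return net


def _read_sbml(path) -> MetabolicNetwork:
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise NetworkParseError(
                f"{path}: line {err.getLine()}: {err.getMessage().strip()}"
            )
    model = doc.getModel()
    if model is None:
        raise NetworkParseError(f"{path}: no SBML model element found")

    net = MetabolicNetwork()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        net.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or None,
                boundary=bool(sp.getBoundaryCondition()),
            )
        )

    def side(refs):
        coeffs: dict[str, float] = {}
        for ref in refs:
            mid = ref.getSpecies()
            if mid not in net.metabolites:
                raise NetworkValidationError(
                    f"{path}: reaction {rxn.getId()!r} references undeclared "
                    f"species {mid!r}"
                )
            # stoichiometry defaults to 1 when the attribute is absent
            coeff = ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            if math.isnan(coeff):
                coeff = 1.0
            coeffs[mid] = coeffs.get(mid, 0.0) + coeff
        return coeffs

    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        reversible = rxn.getReversible() if rxn.isSetReversible() else True
        net.add_reaction(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or None,
                reversible=bool(reversible),
                reactants=side(rxn.getListOfReactants()),
                products=side(rxn.getListOfProducts()),
            ),
            create_missing=False,
        )
    return net


def write_network(net: MetabolicNetwork, path, dialect: str = "sbml") -> None:
    """Write ``net`` so that :func:`read_network` inverts it exactly
    (ids, coefficients, reversibility, boundary flags)."""
    if dialect == "idlist":
        with open(path, "w", encoding="utf-8") as fh:
            for mid in sorted(net.metabolites):
                fh.write(mid + "\n")
        return
    if dialect != "sbml":
        raise ValueError(f"unknown dialect {dialect!r}")

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("model")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    for mid in sorted(net.metabolites):
        met = net.metabolites[mid]
        sp = model.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment("c")
        sp.setBoundaryCondition(met.boundary)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)

    for rid in sorted(net.reactions):
        rxn = net.reactions[rid]
        sr = model.createReaction()
        sr.setId(rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for mid in sorted(rxn.reactants):
            ref = sr.createReactant()
            ref.setSpecies(mid)
            ref.setStoichiometry(float(rxn.reactants[mid]))
            ref.setConstant(True)
        for mid in sorted(rxn.products):
            ref = sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(float(rxn.products[mid]))
            ref.setConstant(True)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------

def merge_networks(a: MetabolicNetwork, b: MetabolicNetwork) -> MetabolicNetwork:
    """Union of two networks.

    Idempotent and commutative up to ordering.  A reaction id present in both
    with different content raises :class:`MergeConflictError`.
    """
    clashes = [
        rid
        for rid in set(a.reactions) & set(b.reactions)
        if not a.reactions[rid].same_content(b.reactions[rid])
    ]
    if clashes:
        raise MergeConflictError(clashes)
    met_clashes = [
        mid
        for mid in set(a.metabolites) & set(b.metabolites)
        if a.metabolites[mid].boundary != b.metabolites[mid].boundary
    ]
    if met_clashes:
        raise MergeConflictError(met_clashes)

    out = MetabolicNetwork()
    for net in (a, b):
        for m in net.metabolites.values():
            if m.id not in out.metabolites:
                out.add_metabolite(m)
        for r in net.reactions.values():
            if r.id not in out.reactions:
                out.add_reaction(r)
    return out


def directed_view(net: MetabolicNetwork) -> list[DirectedReaction]:
    """Expand to directed reactions: one forward per reaction plus one
    backward per reversible reaction, in deterministic id order."""
    out: list[DirectedReaction] = []
    for rid in sorted(net.reactions):
        rxn = net.reactions[rid]
        fwd = DirectedReaction(
            origin_id=rid,
            direction="forward",
            reactants=frozenset(rxn.reactants),
            products=frozenset(rxn.products),
        )
        out.append(fwd)
        if rxn.reversible:
            out.append(
                DirectedReaction(
                    origin_id=rid,
                    direction="backward",
                    reactants=fwd.products,
                    products=fwd.reactants,
                )
            )
    return out
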