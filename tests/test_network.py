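"""Domain types, SBML / id-list I/O and structural operations."""

import pytest

from topofill import (
    GapFillInstance,
    MergeConflictError,
    MetabolicNetwork,
    Metabolite,
    NetworkParseError,
    NetworkValidationError,
    Reaction,
    compute_scope,
    directed_view,
    merge_networks,
    read_network,
    write_network,
)
from topofill.fixtures import fig1_instance, fig2_network, random_instance

SBML_MINIMAL = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="m">
    <listOfCompartments><compartment id="c"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c"/>
      <species id="B" compartment="c" boundaryCondition="true"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r1" reversible="false">
        <listOfReactants><speciesReference species="A"/></listOfReactants>
        <listOfProducts><speciesReference species="B" stoichiometry="2"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


class TestReactionInvariants:
    def test_nonpositive_coefficient_rejected(self):
        with pytest.raises(NetworkValidationError):
            Reaction(id="r", reactants={"a": 0.0}, products={"b": 1.0})
        with pytest.raises(NetworkValidationError):
            Reaction(id="r", reactants={"a": -1.0}, products={"b": 1.0})

    def test_both_sides_empty_rejected(self):
        with pytest.raises(NetworkValidationError):
            Reaction(id="r")

    def test_metabolite_on_both_sides_allowed(self):
        r = Reaction(id="r", reactants={"a": 1.0}, products={"a": 2.0})
        assert r.reactants["a"] == 1.0 and r.products["a"] == 2.0

    def test_one_sided_reactions_allowed(self):
        Reaction(id="source", products={"a": 1.0})
        Reaction(id="sink", reactants={"a": 1.0})


class TestSbmlIO:
    def test_minimal_level2_document(self, tmp_path):
        p = tmp_path / "m.sbml"
        p.write_text(SBML_MINIMAL)
        net = read_network(p)
        assert set(net.metabolites) == {"A", "B"}
        assert net.metabolites["B"].boundary and not net.metabolites["A"].boundary
        rxn = net.reactions["r1"]
        assert not rxn.reversible
        assert rxn.reactants == {"A": 1.0}  # default stoichiometry 1
        assert rxn.products == {"B": 2.0}

    def test_malformed_xml_names_line(self, tmp_path):
        p = tmp_path / "bad.sbml"
        p.write_text("<sbml><unclosed>")
        with pytest.raises(NetworkParseError, match="line"):
            read_network(p)

    def test_undeclared_species_rejected(self, tmp_path):
        p = tmp_path / "bad.sbml"
        p.write_text(SBML_MINIMAL.replace('species="A"/></listOfReactants>',
                                          'species="GHOST"/></listOfReactants>'))
        with pytest.raises(NetworkValidationError, match="GHOST"):
            read_network(p)

    @pytest.mark.parametrize(
        "net",
        [
            MetabolicNetwork(),
            fig1_instance().draft,
            fig1_instance().database,
            fig2_network()[0],
            random_instance(7).database,
        ],
        ids=["empty", "fig1-draft", "fig1-db", "fig2", "random"],
    )
    def test_round_trip_identity(self, tmp_path, net):
        """read(write(net)) preserves ids, coefficients, reversibility and
        boundary flags exactly."""
        p = tmp_path / "rt.sbml"
        write_network(net, p)
        assert read_network(p).content_equal(net)

    def test_reversible_flag_round_trips(self, tmp_path):
        net = MetabolicNetwork()
        net.add_reaction(Reaction(id="r", reactants={"a": 1.0},
                                  products={"b": 1.0}, reversible=True))
        p = tmp_path / "rev.sbml"
        write_network(net, p)
        assert b'reversible="true"' in p.read_bytes()
        assert read_network(p).reactions["r"].reversible


class TestIdList:
    def test_idlist_parses_ids_only(self, tmp_path):
        p = tmp_path / "seeds.txt"
        p.write_text("NAD\nATP\n\n# comment\nH2O  # inline\n")
        net = read_network(p)
        assert set(net.metabolites) == {"NAD", "ATP", "H2O"}
        assert not net.reactions

    def test_idlist_rejects_multi_token_lines(self, tmp_path):
        p = tmp_path / "seeds.txt"
        p.write_text("NAD ATP\n")
        with pytest.raises(NetworkParseError):
            read_network(p)


class TestMerge:
    def test_empty_is_identity(self, fig1):
        merged = merge_networks(fig1.draft, MetabolicNetwork())
        assert merged.content_equal(fig1.draft)

    def test_disjoint_union(self):
        a = MetabolicNetwork(reactions=[Reaction(id="r1", reactants={"a": 1.0}, products={"b": 1.0})])
        b = MetabolicNetwork(reactions=[Reaction(id="r2", reactants={"c": 1.0}, products={"d": 1.0})])
        assert set(merge_networks(a, b).reactions) == {"r1", "r2"}

    def test_idempotent_and_commutative(self, fig1):
        a, b = fig1.draft, fig1.database
        assert merge_networks(a, a).content_equal(a)
        assert merge_networks(a, b).content_equal(merge_networks(b, a))

    def test_associative(self, fig1):
        a, b = fig1.draft, fig1.database
        c = MetabolicNetwork(reactions=[Reaction(id="z", reactants={"q": 1.0}, products={"S": 1.0})])
        left = merge_networks(merge_networks(a, b), c)
        right = merge_networks(a, merge_networks(b, c))
        assert left.content_equal(right)

    def test_conflicting_definition_rejected(self):
        a = MetabolicNetwork(reactions=[Reaction(id="r", reactants={"a": 1.0}, products={"b": 1.0})])
        b = MetabolicNetwork(reactions=[Reaction(id="r", reactants={"a": 2.0}, products={"b": 1.0})])
        with pytest.raises(MergeConflictError, match="r"):
            merge_networks(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_never_shrinks_scope(self, seed):
        inst = random_instance(seed)
        seeds = inst.seeds
        alone = compute_scope(directed_view(inst.draft), seeds).producible
        merged = compute_scope(
            directed_view(merge_networks(inst.draft, inst.database)), seeds
        ).producible
        assert alone <= merged


class TestDirectedView:
    def test_irreversible_gives_one_direction(self):
        net = MetabolicNetwork(reactions=[Reaction(id="r", reactants={"a": 1.0}, products={"b": 1.0})])
        dirs = directed_view(net)
        assert len(dirs) == 1 and dirs[0].direction == "forward"

    def test_reversible_swaps_sides(self):
        net = MetabolicNetwork(reactions=[
            Reaction(id="r", reactants={"a": 1.0}, products={"b": 1.0}, reversible=True)
        ])
        fwd, bwd = directed_view(net)
        assert bwd.reactants == fwd.products and bwd.products == fwd.reactants

    @pytest.mark.parametrize("seed", range(5))
    def test_count_is_reactions_plus_reversibles(self, seed):
        net = random_instance(seed, p_reversible=0.5).database
        n_rev = sum(r.reversible for r in net.reactions.values())
        assert len(directed_view(net)) == len(net.reactions) + n_rev


class TestGapFillInstance:
    def test_empty_seed_or_target_rejected(self, fig1):
        with pytest.raises(NetworkValidationError):
            GapFillInstance(fig1.draft, fig1.database, frozenset(), fig1.targets)
        with pytest.raises(NetworkValidationError):
            GapFillInstance(fig1.draft, fig1.database, fig1.seeds, frozenset())

    def test_shared_id_must_match(self, fig1):
        db = fig1.database.copy()
        db.add_reaction(Reaction(id="D1", reactants={"c1": 1.0}, products={"T1": 1.0}))
        with pytest.raises(MergeConflictError):
            GapFillInstance(fig1.draft, db, fig1.seeds, fig1.targets)

    def test_identical_shared_id_deduplicated(self, fig1):
        db = fig1.database.copy()
        db.add_reaction(fig1.draft.reactions["D1"])
        inst = GapFillInstance(fig1.draft, db, fig1.seeds, fig1.targets)
        assert "D1" not in inst.database_only_ids
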