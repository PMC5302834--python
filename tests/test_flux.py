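"""FBA/FVA validation layer: functionality and reaction classification."""

import pytest

from topofill import (
    MetabolicNetwork,
    NonFunctionalModelError,
    Reaction,
    TopofillError,
    add_demand,
    build_flux_model,
    classify_reactions,
    fba_max,
)
from topofill.fixtures import benchmark_model, fig2_network
from topofill.reference import knockout_essential


def _chain_net():
    """S -> a -> T with a biomass reaction consuming T."""
    net = MetabolicNetwork()
    net.add_reaction(Reaction(id="r1", reactants={"S": 1.0}, products={"a": 1.0}))
    net.add_reaction(Reaction(id="r2", reactants={"a": 1.0}, products={"T": 1.0}))
    net.add_reaction(Reaction(id="bio", reactants={"T": 1.0}))
    return net


def _parallel_net():
    net = MetabolicNetwork()
    net.add_reaction(Reaction(id="rA", reactants={"S": 1.0}, products={"T": 1.0}))
    net.add_reaction(Reaction(id="rB", reactants={"S": 1.0}, products={"T": 1.0}))
    net.add_reaction(Reaction(id="bio", reactants={"T": 1.0}))
    return net


class TestBuildFluxModel:
    def test_one_exchange_per_seed(self):
        net = MetabolicNetwork(
            reactions=[Reaction(id="r", reactants={"S": 1.0}, products={"T": 1.0})]
        )
        model = build_flux_model(net, {"S"}, "r")
        assert len(model.network.reactions) == 2
        assert model.exchange_ids == {"EX_S"}
        assert model.bounds["EX_S"] == (0.0, 1000.0)

    def test_missing_objective_rejected(self):
        net = MetabolicNetwork(
            reactions=[Reaction(id="r", reactants={"S": 1.0}, products={"T": 1.0})]
        )
        with pytest.raises(TopofillError):
            build_flux_model(net, {"S"}, "nope")

    def test_matrix_dimensions(self):
        net, seeds, bio = benchmark_model(n_modules=2, chain_len=3, branch_len=2, n_blocked=2)
        model = build_flux_model(net, seeds, bio)
        rows, S = model.stoichiometric_matrix()
        n_nonboundary = sum(
            not m.boundary for m in model.network.metabolites.values()
        )
        assert S.shape == (n_nonboundary, len(net.reactions) + len(seeds))

    def test_boundary_metabolites_excluded_from_balance(self):
        net = MetabolicNetwork()
        net.add_metabolite(__import__("topofill").Metabolite("waste", boundary=True))
        net.add_reaction(Reaction(id="r", reactants={"S": 1.0}, products={"T": 1.0, "waste": 1.0}))
        net.add_reaction(Reaction(id="bio", reactants={"T": 1.0}))
        model = build_flux_model(net, {"S"}, "bio")
        assert float(fba_max(model)) > 0  # waste may accumulate freely


class TestFbaMax:
    def test_seeded_chain_is_functional(self):
        model = build_flux_model(_chain_net(), {"S"}, "bio")
        assert float(fba_max(model)) == pytest.approx(1000.0)

    def test_without_seed_import_flux_is_zero(self):
        model = build_flux_model(_chain_net(), set(), "bio")
        assert float(fba_max(model)) == pytest.approx(0.0, abs=1e-9)

    def test_stoichiometric_branch_blocks_t1_unless_n_is_2(self):
        for n, expected_positive in [(1.0, False), (2.0, True), (3.0, False)]:
            net, seeds = fig2_network(n=n)
            model = build_flux_model(add_demand(net, ["T1"], "DM"), seeds, "DM")
            assert (float(fba_max(model)) > 1e-6) is expected_positive

    def test_cycle_metabolite_carries_fba_flux(self, fig2):
        """The j/k/l loop nets one k per turn, so k is FBA-producible even
        though it has no topological route from the seed."""
        net, seeds = fig2
        model = build_flux_model(add_demand(net, ["k"], "DM"), seeds, "DM")
        assert float(fba_max(model)) > 1.0

    def test_accumulating_byproduct_blocks_t2(self, fig2):
        net, seeds = fig2
        model = build_flux_model(add_demand(net, ["T2"], "DM"), seeds, "DM")
        assert float(fba_max(model)) == pytest.approx(0.0, abs=1e-6)

    def test_joint_t3_t4_objective_feasible(self, fig2):
        net, seeds = fig2
        model = build_flux_model(add_demand(net, ["T3", "T4"], "DM"), seeds, "DM")
        assert float(fba_max(model)) > 1.0


class TestClassification:
    def test_linear_chain_all_essential(self):
        model = build_flux_model(_chain_net(), {"S"}, "bio")
        classes = classify_reactions(model)
        assert classes.essential >= {"r1", "r2", "bio"}
        assert not classes.alternative - {"EX_S"}

    def test_parallel_routes_both_alternative(self):
        model = build_flux_model(_parallel_net(), {"S"}, "bio")
        classes = classify_reactions(model)
        assert {"rA", "rB"} <= classes.alternative

    def test_classes_partition_reactions(self):
        net, seeds, bio = benchmark_model(n_modules=2, chain_len=3, branch_len=2, n_blocked=2)
        model = build_flux_model(net, seeds, bio)
        classes = classify_reactions(model)
        assert set(classes.labels) == set(model.network.reactions)
        assert set(classes.labels.values()) <= {"essential", "alternative", "blocked"}

    def test_nonfunctional_model_rejected(self):
        model = build_flux_model(_chain_net(), set(), "bio")
        with pytest.raises(NonFunctionalModelError):
            classify_reactions(model)

    @pytest.mark.parametrize(
        "cfg",
        [
            dict(n_modules=1, chain_len=3, branch_len=2, n_blocked=2),
            dict(n_modules=2, chain_len=2, branch_len=2, n_blocked=2),
            dict(n_modules=1, chain_len=5, branch_len=2, n_blocked=4),
        ],
    )
    def test_essential_agrees_with_knockout_oracle(self, cfg):
        """FVA essentiality == single knock-out kills biomass."""
        net, seeds, bio = benchmark_model(**cfg)
        model = build_flux_model(net, seeds, bio)
        assert classify_reactions(model).essential == knockout_essential(model)

    def test_blocked_reactions_removable_without_flux_change(self):
        net, seeds, bio = benchmark_model(n_modules=1, chain_len=3, branch_len=2, n_blocked=4)
        model = build_flux_model(net, seeds, bio)
        classes = classify_reactions(model)
        blocked = classes.blocked & set(net.reactions)
        assert blocked
        stripped = build_flux_model(net.remove_reactions(blocked), seeds, bio)
        assert float(fba_max(stripped)) == pytest.approx(float(fba_max(model)))

    def test_classification_invariant_under_bound_scaling(self):
        net, seeds, bio = benchmark_model(n_modules=1, chain_len=3, branch_len=2, n_blocked=2)
        small = build_flux_model(net, seeds, bio, default_bound=100.0)
        big = build_flux_model(net, seeds, bio, default_bound=10000.0)
        assert classify_reactions(small).labels == classify_reactions(big).labels


class TestAgainstCobrapy:
    """Independent cross-check of the LP layer against cobrapy+GLPK."""

    def _to_cobra(self, model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("xcheck")
        mets = {
            mid: cobra.Metabolite(mid, compartment="c")
            for mid, m in model.network.metabolites.items()
            if not m.boundary
        }
        rxns = []
        for rid in model.reaction_order:
            rxn = model.network.reactions[rid]
            cr = cobra.Reaction(rid)
            cr.lower_bound, cr.upper_bound = model.bounds[rid]
            stoich = {}
            for mid, coeff in rxn.reactants.items():
                if mid in mets:
                    stoich[mets[mid]] = stoich.get(mets[mid], 0.0) - coeff
            for mid, coeff in rxn.products.items():
                if mid in mets:
                    stoich[mets[mid]] = stoich.get(mets[mid], 0.0) + coeff
            cr.add_metabolites(stoich)
            rxns.append(cr)
        cm.add_reactions(rxns)
        cm.objective = model.objective_id
        return cm

    def test_fba_optimum_matches(self):
        net, seeds, bio = benchmark_model(n_modules=2, chain_len=3, branch_len=2, n_blocked=2)
        model = build_flux_model(net, seeds, bio)
        cm = self._to_cobra(model)
        assert float(fba_max(model)) == pytest.approx(
            cm.optimize().objective_value, rel=1e-6
        )

    def test_fva_intervals_match(self):
        from cobra.flux_analysis import flux_variability_analysis

        net, seeds, bio = benchmark_model(n_modules=1, chain_len=3, branch_len=2, n_blocked=2)
        model = build_flux_model(net, seeds, bio)
        classes = classify_reactions(model, delta=1.0)
        cm = self._to_cobra(model)
        cm.reactions.get_by_id(bio).lower_bound = 1.0
        fva = flux_variability_analysis(cm, fraction_of_optimum=0.0)
        for rid, (lo, hi) in classes.intervals.items():
            assert lo == pytest.approx(fva.loc[rid, "minimum"], abs=1e-5)
            assert hi == pytest.approx(fva.loc[rid, "maximum"], abs=1e-5)
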