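"""LP core: FBA, FVA, duality and shadow prices against independent oracles."""

import math

import numpy as np
import pytest

from halophb.core import MetabolicModel, Metabolite, Reaction
from halophb.fba import (
    InfeasibleProblemError,
    LinearConstraint,
    shadow_price_of_uptake,
    solve_fba,
    solve_fba_fixed_uptakes,
    solve_fva,
)
from halophb.synthetic import random_small_network

from oracles import brute_force_fba, finite_difference_shadow_price


def chain_model():
    """A_ext -> A -> biomass, all 1:1, uptake capped at 10."""
    return MetabolicModel(
        id="chain",
        metabolites=[Metabolite("a_e", compartment="e"),
                     Metabolite("a_c", compartment="c")],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, -10.0, 0.0),
            Reaction("At", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0),
            Reaction("GROWTH", {"a_c": -1.0}, 0.0, 1000.0),
        ],
        objective_reaction_id="GROWTH",
    )


def parallel_model():
    """Two equivalent routes from substrate to product, total capped at 10."""
    return MetabolicModel(
        id="parallel",
        metabolites=[Metabolite("a_e", compartment="e"),
                     Metabolite("a_c", compartment="c"),
                     Metabolite("b_c", compartment="c")],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, -10.0, 0.0),
            Reaction("At", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0),
            Reaction("P1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
            Reaction("P2", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
            Reaction("GROWTH", {"b_c": -1.0}, 0.0, 1000.0),
        ],
        objective_reaction_id="GROWTH",
    )


class TestFBA:
    def test_closed_uptakes_give_zero_objective(self):
        model = chain_model()
        model.set_bounds("EX_a", 0.0, 0.0)
        sol = solve_fba(model)
        assert sol.is_optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)

    def test_linear_chain_hits_uptake_bound(self):
        sol = solve_fba(chain_model())
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert sol.fluxes["EX_a"] == pytest.approx(-10.0, abs=1e-9)

    def test_forcing_a_blocked_reaction_is_infeasible(self):
        model = chain_model()
        model.set_bounds("EX_a", 0.0, 0.0)
        sol = solve_fba(model, extra_constraints=[
            LinearConstraint.equality({"GROWTH": 1.0}, 5.0, name="force")
        ])
        assert sol.status == "infeasible"
        assert not sol.fluxes

    def test_steady_state_and_bounds_hold_at_optimum(self, mini_halo,
                                                     default_medium):
        from halophb.core import apply_medium

        constrained = apply_medium(mini_halo, default_medium)
        sol = solve_fba(constrained)
        S = constrained.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in constrained.reaction_ids])
        assert np.max(np.abs(S @ v)) < 1e-6
        for rxn in constrained.reactions:
            assert rxn.lower_bound - 1e-9 <= sol.fluxes[rxn.id] \
                <= rxn.upper_bound + 1e-9


class TestOracleSweep:
    """FBA must agree with exhaustive vertex enumeration on random networks."""

    @pytest.mark.parametrize("seed", range(30))
    def test_random_networks_match_vertex_enumeration(self, seed):
        model = random_small_network(n_mets=4, n_rxns=6, seed=seed)
        expected = brute_force_fba(model)
        sol = solve_fba(model)
        assert expected is not None  # zero flux is always feasible
        assert sol.is_optimal
        assert sol.objective_value == pytest.approx(expected, abs=1e-7)

    def test_strong_duality_on_mini_halo(self, mini_halo, default_medium):
        from halophb.core import apply_medium

        constrained = apply_medium(mini_halo, default_medium)
        sol = solve_fba(constrained)
        # dual objective: sum over bound duals times the active bounds
        dual_value = 0.0
        for rxn in constrained.reactions:
            pi = sol.bound_duals[rxn.id]
            if pi > 1e-12:
                dual_value += pi * rxn.upper_bound
            elif pi < -1e-12:
                dual_value += pi * rxn.lower_bound
        assert dual_value == pytest.approx(sol.objective_value, abs=1e-7)


class TestFVA:
    def test_blocked_reaction_has_zero_range(self, mini_halo):
        ranges = solve_fva(mini_halo, medium={}, reactions=["PHAC"],
                           objective_fraction=0.0)
        assert ranges[0].min_flux == pytest.approx(0.0, abs=1e-9)
        assert ranges[0].max_flux == pytest.approx(0.0, abs=1e-9)

    def test_parallel_paths_share_total_flux(self):
        ranges = {
            fr.reaction_id: fr
            for fr in solve_fva(parallel_model(), reactions=["P1", "P2"],
                                objective_fraction=1.0)
        }
        for rid in ("P1", "P2"):
            assert ranges[rid].min_flux == pytest.approx(0.0, abs=1e-9)
            assert ranges[rid].max_flux == pytest.approx(10.0, abs=1e-9)

    def test_objective_reaction_pinned_at_fraction_one(self, mini_halo,
                                                       default_medium):
        ranges = solve_fva(mini_halo, medium=default_medium,
                           reactions=["BIOMASS"], objective_fraction=1.0)
        assert ranges[0].min_flux == pytest.approx(4.0, abs=1e-6)
        assert ranges[0].max_flux == pytest.approx(4.0, abs=1e-6)

    def test_ranges_contain_fba_optimum_fluxes(self, mini_halo,
                                               default_medium):
        sol = solve_fba(mini_halo, medium=default_medium)
        ranges = solve_fva(mini_halo, medium=default_medium,
                           objective_fraction=1.0)
        for fr in ranges:
            assert fr.min_flux - 1e-6 <= sol.fluxes[fr.reaction_id] \
                <= fr.max_flux + 1e-6
            assert fr.min_flux <= fr.max_flux + 1e-9

    def test_infeasible_base_problem_raises(self):
        model = chain_model()
        model.set_bounds("GROWTH", 20.0, 30.0)  # beyond uptake capacity
        with pytest.raises(InfeasibleProblemError):
            solve_fva(model)


class TestShadowPrices:
    def test_limiting_nutrient_has_positive_price(self, mini_halo,
                                                  aerobic_medium):
        price = shadow_price_of_uptake(mini_halo, aerobic_medium, "EX_glu", 1.0)
        assert price == pytest.approx(2.0, abs=1e-6)

    def test_nutrient_in_excess_has_zero_price(self, mini_halo, aerobic_medium):
        price = shadow_price_of_uptake(mini_halo, aerobic_medium, "EX_glc", 8.0)
        assert price == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("exchange, rate", [
        ("EX_glu", 0.5), ("EX_glu", 1.5), ("EX_glc", 3.0), ("EX_glc", 8.0),
    ])
    def test_matches_central_finite_differences(self, mini_halo,
                                                aerobic_medium, exchange,
                                                rate):
        dual = shadow_price_of_uptake(mini_halo, aerobic_medium, exchange, rate)
        fd = finite_difference_shadow_price(
            mini_halo, aerobic_medium, exchange, rate, solve_fba_fixed_uptakes
        )
        assert dual == pytest.approx(fd, abs=1e-4)

    def test_forced_uptake_beyond_disposal_is_infeasible(self, mini_halo):
        # without oxygen the cell cannot burn forced excess glucose
        anaerobic = {"EX_glc": (-10.0, 0.0), "EX_glu": (-2.0, 0.0)}
        price = shadow_price_of_uptake(mini_halo, anaerobic, "EX_glc", 10.0)
        assert math.isnan(price)


class TestCobraCrossCheck:
    """The scipy/HiGHS path must agree with an independent solver stack."""

    def test_fba_matches_cobrapy_glpk(self, mini_halo, default_medium):
        from halophb.core import apply_medium
        from halophb.io import to_cobra

        constrained = apply_medium(mini_halo, default_medium)
        cm = to_cobra(constrained)
        cobra_mu = cm.optimize().objective_value
        ours = solve_fba(constrained).objective_value
        assert ours == pytest.approx(cobra_mu, abs=1e-6)
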