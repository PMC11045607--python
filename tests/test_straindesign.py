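"""Flux coupling, MUST sets and FORCE-set search on mini-Halo."""

import pytest

from halophb.fba import FluxRange
from halophb.straindesign import (
    Intervention,
    candidate_interventions,
    essential_reactions,
    first_order_must,
    flux_coupling,
    force_set_search,
    second_order_must,
    worst_case_product,
    wt_and_over_ranges,
)

TARGET_FRACTION = 0.9


@pytest.fixture(scope="module")
def design_medium():
    return {"EX_glc": (-10.0, 0.0), "EX_glu": (-2.0, 0.0),
            "EX_o2": (-1000.0, 0.0)}


@pytest.fixture(scope="module")
def ranges(mini_halo, design_medium):
    wt, over, p_max = wt_and_over_ranges(mini_halo, design_medium, "EX_phb",
                                         TARGET_FRACTION)
    return wt, over, p_max


class TestFluxCoupling:
    def test_series_pathway_fully_coupled(self, mini_halo, design_medium):
        relations, _ = flux_coupling(mini_halo, design_medium,
                                     ["PHAA", "PHAB", "PHAC"])
        assert all(r.classification == "full" for r in relations)
        assert all(r.ratio_min == pytest.approx(1.0, abs=1e-6)
                   for r in relations)

    def test_parallel_branches_uncoupled(self, mini_halo, design_medium):
        relations, _ = flux_coupling(mini_halo, design_medium,
                                     ["PHAC", "FAS"])
        assert relations[0].classification == "uncoupled"

    def test_blocked_reaction_excluded_with_note(self, mini_halo):
        # without arginine in the medium its transporter is blocked
        relations, blocked = flux_coupling(
            mini_halo, {"EX_glc": (-10.0, 0.0), "EX_glu": (-2.0, 0.0),
                        "EX_o2": (-1000.0, 0.0)},
            ["ARGt", "PHAA", "PHAB"],
        )
        assert "ARGt" in blocked
        queried = {r.reaction_a for r in relations} | \
            {r.reaction_b for r in relations}
        assert "ARGt" not in queried


class TestRanges:
    def test_overproduction_requires_synthase_flux(self, ranges):
        wt, over, _ = ranges
        assert over["PHAC"].min_flux > wt["PHAC"].max_flux + 1e-6

    def test_target_fraction_zero_equals_plain_fva(self, mini_halo,
                                                   design_medium):
        from halophb.fba import solve_fva

        _, over, _ = wt_and_over_ranges(mini_halo, design_medium, "EX_phb",
                                        0.0, reactions=["PHAC", "FAS"])
        plain = {fr.reaction_id: fr
                 for fr in solve_fva(mini_halo, medium=design_medium,
                                     reactions=["PHAC", "FAS"],
                                     objective_fraction=0.0)}
        for rid in ("PHAC", "FAS"):
            assert over[rid].min_flux == pytest.approx(plain[rid].min_flux,
                                                       abs=1e-6)
            assert over[rid].max_flux == pytest.approx(plain[rid].max_flux,
                                                       abs=1e-6)

    def test_blocked_product_rejected(self, mini_halo, design_medium):
        blocked = mini_halo.copy()
        blocked.set_bounds("EX_phb", 0.0, 0.0)
        with pytest.raises(ValueError, match="nothing to force"):
            wt_and_over_ranges(blocked, design_medium, "EX_phb", 0.9)


class TestFirstOrderMust:
    def test_identical_ranges_give_empty_sets(self):
        ranges = {"r": FluxRange("r", 0.0, 1.0)}
        must_u, must_l = first_order_must(ranges, ranges)
        assert must_u == set() and must_l == set()

    def test_shifted_up_interval_lands_in_must_u(self):
        wt = {"r": FluxRange("r", 0.0, 1.0)}
        over = {"r": FluxRange("r", 2.0, 3.0)}
        must_u, must_l = first_order_must(wt, over)
        assert must_u == {"r"} and must_l == set()

    def test_shifted_down_interval_lands_in_must_l(self):
        wt = {"r": FluxRange("r", 0.0, 1.0)}
        over = {"r": FluxRange("r", -3.0, -2.0)}
        must_u, must_l = first_order_must(wt, over)
        assert must_l == {"r"} and must_u == set()

    def test_mini_halo_placements(self, ranges):
        """PHB synthesis must rise, the lipid drain must fall."""
        wt, over, _ = ranges
        must_u, must_l = first_order_must(wt, over)
        assert "PHAC" in must_u
        assert {"PHAA", "PHAB"} <= must_u
        assert "FAS" in must_l
        assert not must_u & must_l


class TestSecondOrderMust:
    def test_first_order_pair_appears_in_second_order(self, mini_halo,
                                                      design_medium):
        sets = second_order_must(mini_halo, design_medium, "EX_phb",
                                 TARGET_FRACTION,
                                 [("PHAA", "PHAB"), ("PHAC", "FAS")])
        assert ("PHAA", "PHAB") in sets.must_uu
        assert ("PHAC", "FAS") in sets.must_ul

    def test_unrelated_pair_absent(self, mini_halo, design_medium):
        sets = second_order_must(mini_halo, design_medium, "EX_phb",
                                 0.0, [("NADPHOX", "GLUDEG")])
        assert not (sets.must_uu | sets.must_ll | sets.must_ul)


class TestForceSearch:
    def test_singleton_synthase_upregulation_suffices(self, mini_halo,
                                                      design_medium, ranges):
        wt, over, p_max = ranges
        must_u, must_l = first_order_must(wt, over)
        essential = essential_reactions(mini_halo, design_medium,
                                        sorted(must_u | must_l))
        candidates = candidate_interventions(mini_halo, design_medium,
                                             must_u, must_l, over,
                                             exclude=essential)
        result = force_set_search(mini_halo, design_medium, candidates,
                                  "EX_phb",
                                  target_product=TARGET_FRACTION * p_max,
                                  max_size=3, growth_fraction=0.1)
        assert result.sets, "no FORCE set found"
        best = result.sets[0]
        assert len(best.interventions) == 1
        assert best.interventions[0].kind == "up"
        assert best.guaranteed_product >= TARGET_FRACTION * p_max - 1e-9

    def test_returned_sets_are_minimal(self, mini_halo, design_medium,
                                       ranges):
        wt, over, p_max = ranges
        must_u, must_l = first_order_must(wt, over)
        candidates = candidate_interventions(mini_halo, design_medium,
                                             must_u, must_l, over)
        result = force_set_search(mini_halo, design_medium, candidates,
                                  "EX_phb",
                                  target_product=TARGET_FRACTION * p_max,
                                  max_size=2, growth_fraction=0.1)
        target = result.target_product
        for fs in result.sets:
            for k in range(len(fs.interventions)):
                subset = fs.interventions[:k] + fs.interventions[k + 1:]
                if not subset:
                    continue
                worst = worst_case_product(mini_halo, design_medium, "EX_phb",
                                           subset, growth_fraction=0.1)
                assert worst is None or worst < target - 1e-9

    def test_max_size_zero_finds_nothing_beyond_wild_type(self, mini_halo,
                                                          design_medium,
                                                          ranges):
        wt, over, p_max = ranges
        must_u, must_l = first_order_must(wt, over)
        candidates = candidate_interventions(mini_halo, design_medium,
                                             must_u, must_l, over)
        result = force_set_search(mini_halo, design_medium, candidates,
                                  "EX_phb", target_product=0.9 * p_max,
                                  max_size=0)
        assert result.sets == []

    def test_combined_up_and_down_regulation_beats_wild_type(
            self, mini_halo, design_medium, ranges):
        """Raising PHB synthase flux while capping the lipid drain strictly
        increases the worst-case PHB yield over the wild type."""
        wt, over, p_max = ranges
        interventions = (
            Intervention("PHAC", "up", over["PHAC"].min_flux),
            Intervention("FAS", "down", over["FAS"].max_flux),
        )
        wild = worst_case_product(mini_halo, design_medium, "EX_phb", (),
                                  growth_fraction=0.1)
        engineered = worst_case_product(mini_halo, design_medium, "EX_phb",
                                        interventions, growth_fraction=0.1)
        assert engineered is not None
        assert engineered > wild + 0.5 * TARGET_FRACTION * p_max

    def test_intervention_directions_consistent_with_must_sets(
            self, mini_halo, design_medium, ranges):
        wt, over, _ = ranges
        must_u, must_l = first_order_must(wt, over)
        candidates = candidate_interventions(mini_halo, design_medium,
                                             must_u, must_l, over)
        for iv in candidates:
            if iv.kind == "up":
                assert iv.reaction_id in must_u
            else:
                assert iv.reaction_id in must_l
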