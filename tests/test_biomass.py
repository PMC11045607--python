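"""Biomass-equation interpolation, GAM fitting and GA coefficient refinement."""

import pytest

from halophb.biomass import (
    BiomassEquation,
    GAConfig,
    GAMFitError,
    YieldObservation,
    apply_biomass_equation,
    equation_from_model,
    fit_gam,
    interpolate_biomass,
    refine_coefficients,
    sensitivity_rank,
)
from halophb.fba import LinearConstraint, solve_fba

EXCESS = {"EX_glc": (-1000.0, 0.0), "EX_o2": (-1000.0, 0.0),
          "EX_glu": (-1000.0, 0.0)}


def nitrogen_limited_observation(yield_value, condition_id="nlim"):
    """Glutamate-only growth at a unit nitrogen budget."""
    return YieldObservation(
        condition_id=condition_id,
        medium=EXCESS,
        observed_yield=yield_value,
        extra_constraints=(
            LinearConstraint.equality({"EX_glu": -1.0}, 1.0, name="n_budget"),
        ),
    )


def carbon_limited_observation(yield_value, condition_id="clim"):
    return YieldObservation(
        condition_id=condition_id,
        medium={"EX_glc": (-1.0, 0.0), "EX_o2": (-1000.0, 0.0),
                "EX_glu": (-1000.0, 0.0)},
        observed_yield=yield_value,
    )


def observed_yields_from(mini_halo, true_eq):
    """Yields the perturbed-truth equation would produce (the fixture)."""
    truth_model = apply_biomass_equation(mini_halo, true_eq)
    n_obs = nitrogen_limited_observation(1.0)
    mu_n = solve_fba(truth_model, medium=n_obs.medium,
                     extra_constraints=list(n_obs.extra_constraints))
    c_obs = carbon_limited_observation(1.0)
    mu_c = solve_fba(truth_model, medium=c_obs.medium)
    return [
        nitrogen_limited_observation(mu_n.objective_value),
        carbon_limited_observation(mu_c.objective_value),
    ]


class TestInterpolation:
    LOW = BiomassEquation({"a": 2.0, "b": 1.0}, gam_atp=10.0)
    HIGH = BiomassEquation({"a": 4.0, "b": 3.0}, gam_atp=20.0)

    def test_weight_within_salt_interval(self):
        eq = interpolate_biomass(self.LOW, self.HIGH, 0.6, 2.5, 1.0)
        w = (1.0 - 0.6) / (2.5 - 0.6)
        assert eq.coefficients["a"] == pytest.approx(2.0 + w * 2.0)
        assert w == pytest.approx(0.21052631578947367)

    def test_endpoint_returns_reference_equation(self):
        eq = interpolate_biomass(self.LOW, self.HIGH, 0.6, 2.5, 0.6)
        assert eq.coefficients == self.LOW.coefficients
        assert eq.gam_atp == self.LOW.gam_atp

    def test_midpoint_is_arithmetic_mean(self):
        eq = interpolate_biomass(self.LOW, self.HIGH, 0.0, 2.0, 1.0)
        assert eq.coefficients["a"] == pytest.approx(3.0)

    def test_extrapolation_rejected(self):
        with pytest.raises(ValueError, match="extrapolation"):
            interpolate_biomass(self.LOW, self.HIGH, 0.6, 2.5, 3.0)

    def test_linearity_coefficient_wise(self):
        quarter = interpolate_biomass(self.LOW, self.HIGH, 0.0, 1.0, 0.25)
        half = interpolate_biomass(self.LOW, self.HIGH, 0.0, 1.0, 0.5)
        for key in self.LOW.coefficients:
            lo, q, h = (self.LOW.coefficients[key],
                        quarter.coefficients[key], half.coefficients[key])
            assert q - lo == pytest.approx((h - lo) / 2)


class TestFitGAM:
    """On mini-Halo with glucose fixed at 1 and excess nitrogen, growth is
    ATP-limited with closed form mu(GAM) = 32/(25.4 + GAM) once GAM exceeds
    6.6, which inverts exactly."""

    def test_recovers_gam_from_closed_form(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        target_gam = 14.6
        observed = 32.0 / (25.4 + target_gam)
        gam = fit_gam(mini_halo, eq, EXCESS, observed,
                      measured_uptakes={"EX_glc": 1.0})
        assert gam == pytest.approx(target_gam, rel=1e-4)

    def test_observed_at_gam_zero_returns_zero(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        mu0 = 1.0  # carbon-limited optimum at 1 mmol glucose
        assert fit_gam(mini_halo, eq, EXCESS, mu0,
                       measured_uptakes={"EX_glc": 1.0}) == 0.0

    def test_unattainable_growth_reports_maximum(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        with pytest.raises(GAMFitError) as err:
            fit_gam(mini_halo, eq, EXCESS, 5.0,
                    measured_uptakes={"EX_glc": 1.0})
        assert err.value.max_attainable_mu == pytest.approx(1.0, rel=1e-6)

    def test_growth_strictly_decreasing_in_gam_when_atp_limits(self,
                                                               mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        mus = []
        for gam in (10.0, 20.0, 40.0):
            from halophb.biomass import _mu_at_gam

            mus.append(_mu_at_gam(mini_halo, eq, EXCESS,
                                  {"EX_glc": 1.0}, gam))
        assert mus[0] > mus[1] > mus[2]


class TestSensitivity:
    def test_nitrogen_precursor_tops_ranking_under_n_limitation(self,
                                                                mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        obs = [nitrogen_limited_observation(2.0)]
        ranked = sensitivity_rank(mini_halo, eq, obs)
        assert ranked[0][0] == "glu_c"

    def test_unused_precursors_have_zero_sensitivity(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        obs = [nitrogen_limited_observation(2.0)]
        sens = dict(sensitivity_rank(mini_halo, eq, obs))
        # ATP and NADPH are in excess under nitrogen limitation
        assert sens["atp_c"] == pytest.approx(0.0, abs=1e-6)
        assert sens["nadph_c"] == pytest.approx(0.0, abs=1e-6)

    def test_ranking_stable_under_small_perturbation(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        obs = [nitrogen_limited_observation(2.0),
               carbon_limited_observation(0.9)]
        first = [m for m, _ in sensitivity_rank(mini_halo, eq, obs)]
        perturbed = eq.with_coefficients(
            {m: c * 1.01 for m, c in eq.coefficients.items()}
        )
        second = [m for m, _ in sensitivity_rank(mini_halo, perturbed, obs)]
        assert first[:3] == second[:3]


class TestRefinement:
    def test_zero_generations_returns_initial_equation(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        obs = [nitrogen_limited_observation(1.8)]
        fit = refine_coefficients(mini_halo, eq, obs, k_top=1,
                                  config=GAConfig(generations=0, seed=0))
        assert fit.equation.coefficients == eq.coefficients
        assert fit.final_error == fit.initial_error

    def test_single_coefficient_single_observation_converges(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        # truth: glutamate coefficient 0.55 -> yield 1/0.55
        obs = [nitrogen_limited_observation(1.0 / 0.55)]
        fit = refine_coefficients(
            mini_halo, eq, obs, k_top=1,
            config=GAConfig(population_size=30, generations=40, seed=3),
        )
        assert fit.final_error < 1e-3
        assert fit.equation.coefficients["glu_c"] == pytest.approx(0.55,
                                                                   rel=5e-3)

    def test_parameter_recovery_from_perturbed_equation(self, mini_halo):
        """Observations generated from a perturbed truth equation are fit
        back to within 5% per coefficient with final error below 1%."""
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        true_eq = eq.with_coefficients({"glu_c": 0.55, "lipid_c": 0.25})
        obs = observed_yields_from(mini_halo, true_eq)
        fit = refine_coefficients(
            mini_halo, eq, obs, k_top=2,
            config=GAConfig(population_size=40, generations=80, seed=1),
        )
        assert fit.final_error < 0.01
        assert fit.equation.coefficients["glu_c"] == pytest.approx(0.55,
                                                                   rel=0.05)
        assert fit.equation.coefficients["lipid_c"] == pytest.approx(0.25,
                                                                     rel=0.05)

    def test_refinement_never_increases_error(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        obs = [nitrogen_limited_observation(2.0)]  # already exact
        fit = refine_coefficients(
            mini_halo, eq, obs, k_top=1,
            config=GAConfig(population_size=10, generations=5, seed=0),
        )
        assert fit.final_error <= fit.initial_error + 1e-12

    def test_deterministic_given_seed(self, mini_halo):
        eq = equation_from_model(mini_halo, gam_atp=5.0)
        obs = [nitrogen_limited_observation(1.9)]
        cfg = GAConfig(population_size=12, generations=8, seed=5)
        a = refine_coefficients(mini_halo, eq, obs, k_top=1, config=cfg)
        b = refine_coefficients(mini_halo, eq, obs, k_top=1, config=cfg)
        assert a.equation.coefficients == b.equation.coefficients
        assert a.trace == b.trace
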