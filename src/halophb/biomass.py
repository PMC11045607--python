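"""Biomass-equation manipulation and refinement.

The biomass equation lists the precursor drains (mmol per gDCW, positive
for consumed species) plus the growth-associated maintenance ATP (GAM).
Supported operations:

* linear interpolation of coefficients between two reference equations
  measured at different salt concentrations;
* fitting GAM so that the predicted growth rate matches an observed one
  at measured (equality-fixed) uptake rates, by monotone bisection;
* finite-difference sensitivity ranking of precursor coefficients with
  respect to the mean predicted biomass yield;
* refinement of the most sensitive coefficients against observed yields
  with a small elitist genetic algorithm (deterministic given a seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import Medium, MetabolicModel
from .fba import LinearConstraint, solve_fba, solve_fba_fixed_uptakes


class GAMFitError(ValueError):
    """Raised when the observed growth rate is unattainable even at GAM = 0."""

    def __init__(self, message: str, max_attainable_mu: float):
        super().__init__(message)
        self.max_attainable_mu = max_attainable_mu


@dataclass(frozen=True)
class BiomassEquation:
    """Precursor drains (mmol/gDCW, positive = consumed) plus GAM ATP."""

    coefficients: Mapping[str, float]
    gam_atp: float = 0.0
    atp_metabolite: str = "atp_c"

    def __post_init__(self):
        if self.gam_atp < 0:
            raise ValueError("GAM must be >= 0")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    def with_coefficients(self, updates: Mapping[str, float]) -> "BiomassEquation":
        merged = dict(self.coefficients)
        merged.update(updates)
        return replace(self, coefficients=merged)


def apply_biomass_equation(
    model: MetabolicModel,
    eq: BiomassEquation,
    reaction_id: Optional[str] = None,
) -> MetabolicModel:
    """Return a copy with the biomass reaction rebuilt from ``eq``."""
    out = model.copy()
    rid = reaction_id or out.objective_reaction_id
    rxn = out.reaction(rid)
    stoich = {met: -coeff for met, coeff in eq.coefficients.items()}
    if eq.gam_atp:
        stoich[eq.atp_metabolite] = stoich.get(eq.atp_metabolite, 0.0) - eq.gam_atp
    rxn.stoichiometry = stoich
    out.validate()
    return out


def equation_from_model(
    model: MetabolicModel,
    gam_atp: float = 0.0,
    reaction_id: Optional[str] = None,
    atp_metabolite: str = "atp_c",
) -> BiomassEquation:
    """Extract the biomass equation from a model, splitting off ``gam_atp``."""
    rxn = model.reaction(reaction_id or model.objective_reaction_id)
    coeffs = {m: -c for m, c in rxn.stoichiometry.items() if c < 0}
    if gam_atp:
        if coeffs.get(atp_metabolite, 0.0) < gam_atp:
            raise ValueError("GAM exceeds the reaction's total ATP drain")
        coeffs[atp_metabolite] -= gam_atp
    return BiomassEquation(coeffs, gam_atp=gam_atp, atp_metabolite=atp_metabolite)


# ---------------------------------------------------------------------------
# Interpolation across salt conditions
# ---------------------------------------------------------------------------

def interpolate_biomass(
    eq_low: BiomassEquation,
    eq_high: BiomassEquation,
    salt_low: float,
    salt_high: float,
    salt_target: float,
) -> BiomassEquation:
    """Coefficient-wise linear interpolation between two salt conditions.

    The weight is (salt_target - salt_low)/(salt_high - salt_low); the
    target must lie within the closed interval (no extrapolation).
    """
    if salt_low >= salt_high:
        raise ValueError("salt_low must be below salt_high")
    if not salt_low <= salt_target <= salt_high:
        raise ValueError(
            f"target salinity {salt_target} outside [{salt_low}, {salt_high}]; "
            "extrapolation is not supported"
        )
    t = (salt_target - salt_low) / (salt_high - salt_low)
    keys = set(eq_low.coefficients) | set(eq_high.coefficients)
    coeffs = {
        k: (1 - t) * eq_low.coefficients.get(k, 0.0)
        + t * eq_high.coefficients.get(k, 0.0)
        for k in keys
    }
    gam = (1 - t) * eq_low.gam_atp + t * eq_high.gam_atp
    return BiomassEquation(coeffs, gam_atp=gam,
                           atp_metabolite=eq_low.atp_metabolite)


# ---------------------------------------------------------------------------
# GAM fitting
# ---------------------------------------------------------------------------

def _mu_at_gam(model, eq, medium, measured_uptakes, gam) -> float:
    trial = apply_biomass_equation(model, replace(eq, gam_atp=gam))
    if measured_uptakes:
        sol, _ = solve_fba_fixed_uptakes(trial, medium, measured_uptakes)
    else:
        sol = solve_fba(trial, medium=medium)
    return sol.objective_value if sol.is_optimal else 0.0


def fit_gam(
    model: MetabolicModel,
    eq: BiomassEquation,
    medium: Optional[Medium],
    observed_mu: float,
    measured_uptakes: Optional[Mapping[str, float]] = None,
    rel_tol: float = 1e-6,
    gam_initial_bracket: float = 10.0,
    max_gam: float = 1e5,
) -> float:
    """GAM value at which predicted growth equals ``observed_mu``.

    Growth is non-increasing in GAM (more maintenance ATP per unit
    biomass), so monotone bisection applies.  Uptakes in
    ``measured_uptakes`` (magnitudes) are fixed by equality.
    """
    if observed_mu <= 0:
        raise ValueError("observed growth rate must be positive")
    mu0 = _mu_at_gam(model, eq, medium, measured_uptakes, 0.0)
    if observed_mu > mu0 * (1 + rel_tol):
        raise GAMFitError(
            f"observed mu {observed_mu} exceeds the maximum attainable "
            f"{mu0} at GAM=0", max_attainable_mu=mu0,
        )
    if observed_mu >= mu0 * (1 - rel_tol):
        return 0.0
    hi = gam_initial_bracket
    while _mu_at_gam(model, eq, medium, measured_uptakes, hi) > observed_mu:
        hi *= 2
        if hi > max_gam:
            raise GAMFitError(
                f"growth stays above {observed_mu} up to GAM={max_gam}",
                max_attainable_mu=mu0,
            )
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mu = _mu_at_gam(model, eq, medium, measured_uptakes, mid)
        if abs(mu - observed_mu) <= rel_tol * observed_mu:
            return mid
        if mu > observed_mu:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Yield predictions, sensitivity, GA refinement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YieldObservation:
    """An observed biomass yield under a given medium/constraint setting."""

    condition_id: str
    medium: Medium
    observed_yield: float  # gDCW per mmol N (or per the chosen normalizer)
    sd: float = 0.0
    extra_constraints: Tuple[LinearConstraint, ...] = ()

    def __post_init__(self):
        if self.observed_yield <= 0:
            raise ValueError("observed yield must be positive")


def predict_yields(
    model: MetabolicModel,
    eq: BiomassEquation,
    observations: Sequence[YieldObservation],
    zero_ngam: bool = True,
) -> List[float]:
    """Maximum predicted yield (FBA optimum) per observation condition."""
    trial = apply_biomass_equation(model, eq)
    if zero_ngam and trial.ngam_reaction_id:
        ngam = trial.reaction(trial.ngam_reaction_id)
        trial.set_bounds(ngam.id, 0.0, ngam.upper_bound)
    out = []
    for obs in observations:
        sol = solve_fba(trial, medium=obs.medium,
                        extra_constraints=list(obs.extra_constraints))
        out.append(sol.objective_value if sol.is_optimal else 0.0)
    return out


def mean_relative_error(
    model: MetabolicModel,
    eq: BiomassEquation,
    observations: Sequence[YieldObservation],
) -> float:
    """Mean over conditions of |predicted - observed| / observed."""
    preds = predict_yields(model, eq, observations)
    return float(np.mean([
        abs(p - o.observed_yield) / o.observed_yield
        for p, o in zip(preds, observations)
    ]))


def sensitivity_rank(
    model: MetabolicModel,
    eq: BiomassEquation,
    observations: Sequence[YieldObservation],
    rel_step: float = 0.01,
) -> List[Tuple[str, float]]:
    """Precursors ranked by |d(mean yield)/d(coefficient)| (central FD)."""
    base_mean = float(np.mean(predict_yields(model, eq, observations)))
    ranked = []
    for met, coeff in eq.coefficients.items():
        h = rel_step * coeff if coeff != 0 else rel_step
        up = float(np.mean(predict_yields(
            model, eq.with_coefficients({met: coeff + h}), observations)))
        down = float(np.mean(predict_yields(
            model, eq.with_coefficients({met: coeff - h}), observations)))
        ranked.append((met, abs((up - down) / (2 * h))))
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    elitism: int = 1
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_sigma_fraction: float = 0.05  # of the search range
    bounds_fraction: Tuple[float, float] = (0.1, 10.0)  # of initial values
    seed: int = 0


@dataclass
class FitResult:
    equation: BiomassEquation
    initial_error: float
    final_error: float
    per_condition_errors: List[float]
    optimized_metabolites: List[str]
    trace: List[float]  # best error per generation
    seed: int
    improved: bool


def refine_coefficients(
    model: MetabolicModel,
    eq: BiomassEquation,
    observations: Sequence[YieldObservation],
    k_top: int,
    config: Optional[GAConfig] = None,
) -> FitResult:
    """Refine the ``k_top`` most sensitive coefficients against observations.

    An elitist genetic algorithm (tournament selection, uniform crossover,
    Gaussian mutation) minimizes the mean relative yield error; each
    coefficient is bounded to [0.1x, 10x] its initial value by default.
    Elitism guarantees the refined error never exceeds the initial one.
    """
    if not observations:
        raise ValueError("need at least one yield observation")
    if k_top < 1 or k_top > len(eq.coefficients):
        raise ValueError("k_top must be in [1, number of precursors]")
    cfg = config or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    targets = [met for met, _ in
               sensitivity_rank(model, eq, observations)[:k_top]]
    x0 = np.array([eq.coefficients[m] for m in targets])
    lo = cfg.bounds_fraction[0] * x0
    hi = cfg.bounds_fraction[1] * x0
    span = hi - lo

    def error_of(x: np.ndarray) -> float:
        return mean_relative_error(
            model, eq.with_coefficients(dict(zip(targets, x))), observations
        )

    initial_error = error_of(x0)
    pop = np.clip(
        x0 + span * 0.1 * rng.standard_normal((cfg.population_size, len(x0))),
        lo, hi,
    )
    pop[0] = x0  # keep the starting point in the initial population
    fitness = np.array([error_of(ind) for ind in pop])
    trace: List[float] = []
    if cfg.generations > 0:
        for _ in range(cfg.generations):
            order = np.argsort(fitness)
            new_pop = [pop[i].copy() for i in order[:cfg.elitism]]
            while len(new_pop) < cfg.population_size:
                idx = rng.integers(0, cfg.population_size,
                                   size=(2, cfg.tournament_size))
                parents = [
                    pop[row[np.argmin(fitness[row])]] for row in idx
                ]
                child = parents[0].copy()
                if rng.random() < cfg.crossover_rate:
                    mask = rng.random(len(x0)) < 0.5
                    child[mask] = parents[1][mask]
                child += (cfg.mutation_sigma_fraction * span
                          * rng.standard_normal(len(x0)))
                new_pop.append(np.clip(child, lo, hi))
            pop = np.array(new_pop)
            fitness = np.array([error_of(ind) for ind in pop])
            trace.append(float(fitness.min()))
    best_idx = int(np.argmin(fitness))
    best_x, best_err = pop[best_idx], float(fitness[best_idx])
    improved = best_err < initial_error
    if cfg.generations == 0 or not improved:
        best_x, best_err = x0, initial_error
    refined = eq.with_coefficients(dict(zip(targets, best_x)))
    preds = predict_yields(model, refined, observations)
    per_condition = [
        abs(p - o.observed_yield) / o.observed_yield
        for p, o in zip(preds, observations)
    ]
    return FitResult(
        equation=refined,
        initial_error=initial_error,
        final_error=best_err,
        per_condition_errors=per_condition,
        optimized_metabolites=targets,
        trace=trace,
        seed=cfg.seed,
        improved=improved,
    )
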