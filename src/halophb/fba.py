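"""Linear-programming core: FBA, FVA and dual values.

The flux balance problem is

    max  c' v
    s.t. S v = 0,  lb <= v <= ub,  plus optional linear side constraints,

solved with the HiGHS solver through ``scipy.optimize.linprog``.  The
solver sits behind a small contract (``solver=`` keyword) so a different
backend providing duals could be substituted.  All dual values are
reported on the *maximization* scale: a balance dual is d(objective)/d(b)
for the perturbed balance ``S v = b``, a constraint dual is
d(objective)/d(rhs), and a bound dual (reduced cost) is the sensitivity
to the reaction's active bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .core import DEFAULT_BOUND, Medium, MetabolicModel, ModelError, apply_medium

#: Feasibility/optimality tolerances requested from the solver.
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"


class LPError(RuntimeError):
    """Raised when the backend fails for numerical (non-status) reasons."""


class InfeasibleProblemError(RuntimeError):
    """Raised when an operation requires a feasible base problem."""


@dataclass(frozen=True)
class LinearConstraint:
    """Linear side constraint  lb <= sum coeff_i * v_i <= ub.

    Equality is expressed by ``lb == ub``.  ``name`` keys the constraint's
    dual value in the solution.
    """

    coefficients: Mapping[str, float]
    lb: Optional[float] = None
    ub: Optional[float] = None
    name: str = ""

    @staticmethod
    def equality(coefficients: Mapping[str, float], rhs: float,
                 name: str = "") -> "LinearConstraint":
        return LinearConstraint(dict(coefficients), rhs, rhs, name)

    @property
    def is_equality(self) -> bool:
        return self.lb is not None and self.ub is not None and self.lb == self.ub


@dataclass
class FluxSolution:
    status: str
    objective_value: float = math.nan
    fluxes: Dict[str, float] = field(default_factory=dict)
    balance_duals: Dict[str, float] = field(default_factory=dict)
    bound_duals: Dict[str, float] = field(default_factory=dict)
    constraint_duals: Dict[str, float] = field(default_factory=dict)

    @property
    def is_optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


# ---------------------------------------------------------------------------
# Core solve
# ---------------------------------------------------------------------------

def _status_from_scipy(code: int) -> str:
    if code == 0:
        return STATUS_OPTIMAL
    if code == 2:
        return STATUS_INFEASIBLE
    if code == 3:
        return STATUS_UNBOUNDED
    raise LPError(f"solver failed with status code {code}")


def optimize_linear(
    model: MetabolicModel,
    objective: Mapping[str, float],
    medium: Optional[Medium] = None,
    extra_constraints: Sequence[LinearConstraint] = (),
    sense: str = "max",
    solver: str = "highs",
) -> FluxSolution:
    """Optimize an arbitrary linear functional of the fluxes.

    This is the single solver entry point; :func:`solve_fba` and
    :func:`solve_fva` are built on it.
    """
    if solver != "highs":
        raise ValueError(f"unknown solver {solver!r}; available: 'highs'")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    if medium is not None:
        model = apply_medium(model, medium)

    rxn_ids = model.reaction_ids
    met_ids = model.metabolite_ids
    rxn_pos = {rid: j for j, rid in enumerate(rxn_ids)}
    n = len(rxn_ids)

    sign = -1.0 if sense == "max" else 1.0
    c = np.zeros(n)
    for rid, coeff in objective.items():
        if rid not in rxn_pos:
            raise ModelError(f"objective references unknown reaction {rid!r}")
        c[rxn_pos[rid]] = sign * coeff

    S = model.stoichiometric_matrix()
    A_eq_rows: List[np.ndarray] = [S]
    b_eq: List[float] = [0.0] * S.shape[0]
    eq_names: List[Tuple[str, int]] = []  # (constraint name, row index)
    A_ub_rows: List[np.ndarray] = []
    b_ub: List[float] = []
    ub_names: List[Tuple[str, int, float]] = []  # (name, row, sign)

    for k, con in enumerate(extra_constraints):
        row = np.zeros(n)
        for rid, coeff in con.coefficients.items():
            if rid not in rxn_pos:
                raise ModelError(
                    f"constraint {con.name or k} references unknown reaction {rid!r}"
                )
            row[rxn_pos[rid]] = coeff
        name = con.name or f"constraint_{k}"
        if con.is_equality:
            eq_names.append((name, len(b_eq)))
            A_eq_rows.append(row.reshape(1, -1))
            b_eq.append(con.lb)
        else:
            if con.ub is not None:
                ub_names.append((name, len(b_ub), 1.0))
                A_ub_rows.append(row.reshape(1, -1))
                b_ub.append(con.ub)
            if con.lb is not None:
                ub_names.append((name, len(b_ub), -1.0))
                A_ub_rows.append(-row.reshape(1, -1))
                b_ub.append(-con.lb)

    A_eq = np.vstack(A_eq_rows)
    A_ub = np.vstack(A_ub_rows) if A_ub_rows else None
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]

    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.asarray(b_ub) if b_ub else None,
        A_eq=A_eq,
        b_eq=np.asarray(b_eq),
        bounds=bounds,
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": OPTIMALITY_TOL,
        },
    )
    status = _status_from_scipy(res.status)
    if status != STATUS_OPTIMAL:
        return FluxSolution(status=status)

    # scipy reports marginals of the *minimized* objective; flip for "max".
    dual_sign = -1.0 if sense == "max" else 1.0
    eq_marg = np.asarray(res.eqlin.marginals)
    balance_duals = {
        met_ids[i]: dual_sign * eq_marg[i] for i in range(len(met_ids))
    }
    constraint_duals = {
        name: dual_sign * eq_marg[row] for name, row in eq_names
    }
    if A_ub is not None:
        ub_marg = np.asarray(res.ineqlin.marginals)
        for name, row, s in ub_names:
            constraint_duals[name] = (
                constraint_duals.get(name, 0.0) + dual_sign * s * ub_marg[row]
            )
    reduced = np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals)
    bound_duals = {rid: dual_sign * reduced[j] for j, rid in enumerate(rxn_ids)}
    objective_value = -res.fun if sense == "max" else res.fun
    return FluxSolution(
        status=STATUS_OPTIMAL,
        objective_value=float(objective_value),
        fluxes={rid: float(res.x[j]) for j, rid in enumerate(rxn_ids)},
        balance_duals=balance_duals,
        bound_duals=bound_duals,
        constraint_duals=constraint_duals,
    )


def solve_fba(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    extra_constraints: Sequence[LinearConstraint] = (),
    solver: str = "highs",
) -> FluxSolution:
    """Flux balance analysis: maximize the model's objective reaction."""
    model.validate()
    return optimize_linear(
        model,
        {model.objective_reaction_id: 1.0},
        medium=medium,
        extra_constraints=extra_constraints,
        sense="max",
        solver=solver,
    )


def solve_fva(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    reactions: Optional[Iterable[str]] = None,
    objective_fraction: float = 1.0,
    extra_constraints: Sequence[LinearConstraint] = (),
    solver: str = "highs",
) -> List[FluxRange]:
    """Flux variability analysis at a given optimality fraction.

    For each queried reaction, the minimum and maximum flux subject to the
    objective being at least ``objective_fraction`` times its optimum.
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    base = solve_fba(model, medium=medium, extra_constraints=extra_constraints,
                     solver=solver)
    if not base.is_optimal:
        raise InfeasibleProblemError(
            f"FVA base problem is {base.status}; no optimum to constrain against"
        )
    floor = objective_fraction * base.objective_value
    cons = list(extra_constraints) + [
        LinearConstraint({model.objective_reaction_id: 1.0}, lb=floor, ub=None,
                         name="fva_objective_floor")
    ]
    if reactions is None:
        reactions = model.reaction_ids
    ranges = []
    for rid in reactions:
        lo = optimize_linear(model, {rid: 1.0}, medium=medium,
                             extra_constraints=cons, sense="min", solver=solver)
        hi = optimize_linear(model, {rid: 1.0}, medium=medium,
                             extra_constraints=cons, sense="max", solver=solver)
        if not (lo.is_optimal and hi.is_optimal):
            raise LPError(f"FVA subproblem for {rid} returned "
                          f"{lo.status}/{hi.status}")
        ranges.append(FluxRange(rid, lo.objective_value, hi.objective_value))
    return ranges


def solve_fba_fixed_uptakes(
    model: MetabolicModel,
    medium: Optional[Medium],
    fixed_uptakes: Mapping[str, float],
    solver: str = "highs",
) -> Tuple[FluxSolution, Dict[str, float]]:
    """FBA with exchange fluxes fixed by equality to given uptake magnitudes.

    ``fixed_uptakes`` maps exchange ids to uptake magnitudes u >= 0; the
    exchange flux is pinned to -u.  Returns the solution together with the
    shadow price of each fixed uptake, converted so that a positive value
    means more uptake increases the objective.  Infeasible points are
    returned with the infeasible status (they are data, not errors).
    """
    model.validate()
    if medium is not None:
        model = apply_medium(model, medium)
    else:
        model = model.copy()
    exchange_ids = {r.id for r in model.exchanges}
    constraints = []
    for ex_id, rate in fixed_uptakes.items():
        if ex_id not in exchange_ids:
            raise ModelError(f"{ex_id!r} is not an exchange reaction")
        if rate < 0:
            raise ValueError(f"uptake magnitude for {ex_id} must be >= 0")
        # Widen the native bounds so the equality constraint is authoritative.
        model.set_bounds(ex_id, -DEFAULT_BOUND, DEFAULT_BOUND)
        constraints.append(
            LinearConstraint.equality({ex_id: 1.0}, -rate, name=f"fix_{ex_id}")
        )
    sol = optimize_linear(
        model, {model.objective_reaction_id: 1.0},
        extra_constraints=constraints, sense="max", solver=solver,
    )
    prices: Dict[str, float] = {}
    if sol.is_optimal:
        for ex_id in fixed_uptakes:
            # rhs = -u, so d(mu)/du = -d(mu)/d(rhs).
            prices[ex_id] = -sol.constraint_duals[f"fix_{ex_id}"]
    return sol, prices


def shadow_price_of_uptake(
    model: MetabolicModel,
    medium: Optional[Medium],
    exchange_id: str,
    fixed_rate: float,
    solver: str = "highs",
) -> float:
    """Sensitivity of the optimal objective to one nutrient's uptake rate.

    Fixes the exchange flux to ``-fixed_rate`` by equality and returns
    d(objective)/d(uptake magnitude) from the equality's dual.  Positive
    means additional uptake would increase growth.  Returns NaN when the
    equality renders the LP infeasible (a forced-excess point).
    """
    sol, prices = solve_fba_fixed_uptakes(
        model, medium, {exchange_id: fixed_rate}, solver=solver
    )
    if not sol.is_optimal:
        return math.nan
    return prices[exchange_id]
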