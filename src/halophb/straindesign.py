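"""OptForce-style strain design.

The wild-type flux space (growth within a fraction of its maximum) is
contrasted with an overproduction flux space (product forced to a target
fraction of its theoretical maximum).  Reactions whose feasible range
must shift upward to reach the target form the MUST-U set, downward the
MUST-L set; second-order sets classify the sums and differences of
reaction pairs the same way.  FORCE sets are minimal bundles of bound
interventions (up-regulation, down-regulation, knockout) that *guarantee*
the production target: acceptance is checked by a worst-case inner LP
that minimizes product formation subject to the interventions and a
growth requirement.

The original bilevel MILP is replaced by exhaustive subset enumeration
(at most three interventions from a short candidate list) with that
worst-case LP — an identical guarantee on small candidate sets without a
MILP dependency.  Flux coupling analysis provides the shortlisting: the
feasible ratio v_i/v_j (two LPs per ordered pair on the flux cone)
classifies pairs as fully, partially, directionally or un-coupled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .core import Medium, MetabolicModel, apply_medium
from .fba import (
    FluxRange,
    LinearConstraint,
    optimize_linear,
    solve_fba,
    solve_fva,
)

COUPLING_TOL = 1e-6
RANGE_TOL = 1e-6
#: Fluxes at this magnitude of the cone bound are treated as unbounded.
_CONE_BOUND = 1e4


@dataclass(frozen=True)
class CouplingRelation:
    reaction_a: str
    reaction_b: str
    classification: str  # "full", "partial", "directional", "uncoupled"
    ratio_min: float  # range of v_a when v_b is normalized to 1
    ratio_max: float


@dataclass
class MustSets:
    must_u: Set[str] = field(default_factory=set)
    must_l: Set[str] = field(default_factory=set)
    must_uu: Set[Tuple[str, str]] = field(default_factory=set)
    must_ll: Set[Tuple[str, str]] = field(default_factory=set)
    must_ul: Set[Tuple[str, str]] = field(default_factory=set)  # (up, down)


@dataclass(frozen=True)
class Intervention:
    reaction_id: str
    kind: str  # "up", "down", "knockout"
    bound: float  # new lower bound (up) / upper bound (down); ignored for KO


@dataclass(frozen=True)
class ForceSet:
    interventions: Tuple[Intervention, ...]
    guaranteed_product: float  # worst-case product flux under the set


@dataclass
class ForceSearchResult:
    sets: List[ForceSet]
    target_product: float
    best_worst_case: float  # best guaranteed product over all evaluated sets


# ---------------------------------------------------------------------------
# Flux coupling
# ---------------------------------------------------------------------------

def _cone_model(model: MetabolicModel, medium: Optional[Medium]) -> MetabolicModel:
    """Relax finite bounds to the cone scale, keeping directionality."""
    cone = apply_medium(model, medium) if medium is not None else model.copy()
    for rxn in cone.reactions:
        lb = 0.0 if rxn.lower_bound >= 0 else -_CONE_BOUND
        ub = 0.0 if rxn.upper_bound <= 0 else _CONE_BOUND
        rxn.lower_bound, rxn.upper_bound = lb, ub
    return cone


def blocked_reactions(
    model: MetabolicModel, medium: Optional[Medium],
    reactions: Optional[Sequence[str]] = None,
) -> Set[str]:
    """Reactions that can carry no flux at all under the medium."""
    ranges = solve_fva(model, medium=medium, reactions=reactions,
                       objective_fraction=0.0)
    return {
        fr.reaction_id for fr in ranges
        if abs(fr.min_flux) < RANGE_TOL and abs(fr.max_flux) < RANGE_TOL
    }


def _ratio_range(cone: MetabolicModel, target: str, normalized: str):
    """Feasible range of v_target subject to v_normalized = 1."""
    fix = [LinearConstraint.equality({normalized: 1.0}, 1.0, name="normalize")]
    lo = optimize_linear(cone, {target: 1.0}, extra_constraints=fix, sense="min")
    hi = optimize_linear(cone, {target: 1.0}, extra_constraints=fix, sense="max")
    if not (lo.is_optimal and hi.is_optimal):
        return None
    return lo.objective_value, hi.objective_value


def flux_coupling(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    reactions: Optional[Sequence[str]] = None,
) -> Tuple[List[CouplingRelation], Set[str]]:
    """Pairwise coupling classification on the flux cone.

    Returns the relations and the set of blocked reactions that were
    excluded from the query.
    """
    if reactions is None:
        reactions = model.reaction_ids
    blocked = blocked_reactions(model, medium, reactions)
    active = [r for r in reactions if r not in blocked]
    cone = _cone_model(model, medium)
    relations = []
    for a, b in itertools.combinations(active, 2):
        ab = _ratio_range(cone, a, b)  # v_a with v_b = 1
        ba = _ratio_range(cone, b, a)
        if ab is None or ba is None:
            # normalization infeasible: the normalized reaction cannot run
            # forward; treat as uncoupled in this direction
            relations.append(CouplingRelation(a, b, "uncoupled",
                                              math.nan, math.nan))
            continue
        a_can_idle = ab[0] <= COUPLING_TOL <= ab[1] + COUPLING_TOL
        b_can_idle = ba[0] <= COUPLING_TOL <= ba[1] + COUPLING_TOL
        if a_can_idle and b_can_idle:
            label = "uncoupled"
        elif not a_can_idle and not b_can_idle:
            fixed = abs(ab[1] - ab[0]) <= COUPLING_TOL * max(1.0, abs(ab[1]))
            label = "full" if fixed else "partial"
        else:
            label = "directional"
        relations.append(CouplingRelation(a, b, label, ab[0], ab[1]))
    return relations, blocked


# ---------------------------------------------------------------------------
# Wild-type vs overproduction ranges and MUST sets
# ---------------------------------------------------------------------------

def max_product_flux(
    model: MetabolicModel, medium: Optional[Medium], product_exchange: str
) -> float:
    sol = optimize_linear(model, {product_exchange: 1.0}, medium=medium,
                          sense="max")
    if not sol.is_optimal:
        raise ValueError(f"product maximization is {sol.status}")
    return sol.objective_value


def wt_and_over_ranges(
    model: MetabolicModel,
    medium: Optional[Medium],
    product_exchange: str,
    target_fraction: float,
    reactions: Optional[Sequence[str]] = None,
    wt_growth_fraction: float = 0.99,
) -> Tuple[Dict[str, FluxRange], Dict[str, FluxRange], float]:
    """Flux ranges of the wild-type and overproducing phenotypes.

    Wild type: FVA with growth at >= ``wt_growth_fraction`` of its
    maximum.  Overproduction: per-reaction min/max subject to product
    >= ``target_fraction`` x theoretical maximum (growth left free).
    Returns (wt_ranges, over_ranges, theoretical_max_product).
    """
    p_max = max_product_flux(model, medium, product_exchange)
    if p_max <= RANGE_TOL:
        raise ValueError(
            f"theoretical max of {product_exchange} is {p_max}; nothing to force"
        )
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError(f"target_fraction {target_fraction} outside [0, 1] "
                         f"(max attainable product {p_max})")
    if reactions is None:
        reactions = model.reaction_ids
    wt = {
        fr.reaction_id: fr
        for fr in solve_fva(model, medium=medium, reactions=reactions,
                            objective_fraction=wt_growth_fraction)
    }
    floor = LinearConstraint(
        {product_exchange: 1.0}, lb=target_fraction * p_max, ub=None,
        name="production_target",
    )
    over: Dict[str, FluxRange] = {}
    for rid in reactions:
        lo = optimize_linear(model, {rid: 1.0}, medium=medium,
                             extra_constraints=[floor], sense="min")
        hi = optimize_linear(model, {rid: 1.0}, medium=medium,
                             extra_constraints=[floor], sense="max")
        if not (lo.is_optimal and hi.is_optimal):
            raise ValueError(
                f"overproduction regime infeasible for {rid} "
                f"(max attainable product {p_max})"
            )
        over[rid] = FluxRange(rid, lo.objective_value, hi.objective_value)
    return wt, over, p_max


def first_order_must(
    wt_ranges: Mapping[str, FluxRange],
    over_ranges: Mapping[str, FluxRange],
    tol: float = RANGE_TOL,
) -> Tuple[Set[str], Set[str]]:
    """Reactions whose range must shift up (MUST-U) or down (MUST-L)."""
    must_u, must_l = set(), set()
    for rid, over in over_ranges.items():
        if rid not in wt_ranges:
            continue
        wt = wt_ranges[rid]
        if over.min_flux > wt.max_flux + tol:
            must_u.add(rid)
        elif over.max_flux < wt.min_flux - tol:
            must_l.add(rid)
    return must_u, must_l


def _combo_range(model, medium, coeffs, constraints):
    lo = optimize_linear(model, coeffs, medium=medium,
                         extra_constraints=constraints, sense="min")
    hi = optimize_linear(model, coeffs, medium=medium,
                         extra_constraints=constraints, sense="max")
    if not (lo.is_optimal and hi.is_optimal):
        return None
    return lo.objective_value, hi.objective_value


def second_order_must(
    model: MetabolicModel,
    medium: Optional[Medium],
    product_exchange: str,
    target_fraction: float,
    candidate_pairs: Sequence[Tuple[str, str]],
    wt_growth_fraction: float = 0.99,
    tol: float = RANGE_TOL,
) -> MustSets:
    """Second-order MUST sets from sum/difference range shifts of pairs.

    A pair lands in MUST-UU when the *sum* of its fluxes must rise, in
    MUST-LL when the sum must fall, and in MUST-UL (ordered: up-member
    first) when the difference must shift.
    """
    p_max = max_product_flux(model, medium, product_exchange)
    mu_sol = solve_fba(model, medium=medium)
    if not mu_sol.is_optimal:
        raise ValueError("wild-type FBA failed")
    wt_floor = [LinearConstraint(
        {model.objective_reaction_id: 1.0},
        lb=wt_growth_fraction * mu_sol.objective_value, ub=None,
        name="wt_growth_floor",
    )]
    over_floor = [LinearConstraint(
        {product_exchange: 1.0}, lb=target_fraction * p_max, ub=None,
        name="production_target",
    )]
    sets = MustSets()
    for a, b in candidate_pairs:
        for coeffs, kind in (
            ({a: 1.0, b: 1.0}, "sum"),
            ({a: 1.0, b: -1.0}, "diff"),
        ):
            wt = _combo_range(model, medium, coeffs, wt_floor)
            over = _combo_range(model, medium, coeffs, over_floor)
            if wt is None or over is None:
                continue
            if kind == "sum":
                if over[0] > wt[1] + tol:
                    sets.must_uu.add((a, b))
                elif over[1] < wt[0] - tol:
                    sets.must_ll.add((a, b))
            else:
                if over[0] > wt[1] + tol:   # v_a - v_b must rise
                    sets.must_ul.add((a, b))
                elif over[1] < wt[0] - tol:  # v_b - v_a must rise
                    sets.must_ul.add((b, a))
    return sets


# ---------------------------------------------------------------------------
# FORCE set search
# ---------------------------------------------------------------------------

def essential_reactions(
    model: MetabolicModel, medium: Optional[Medium],
    reactions: Sequence[str], threshold_fraction: float = 0.01,
) -> Set[str]:
    """Reactions whose individual removal abolishes growth."""
    wt = solve_fba(model, medium=medium)
    if not wt.is_optimal:
        raise ValueError("wild-type FBA failed")
    essential = set()
    for rid in reactions:
        ko = model.copy()
        ko.set_bounds(rid, 0.0, 0.0)
        sol = solve_fba(ko, medium=medium)
        mu = sol.objective_value if sol.is_optimal else 0.0
        if mu < threshold_fraction * wt.objective_value:
            essential.add(rid)
    return essential


def _apply_interventions(
    model: MetabolicModel, interventions: Sequence[Intervention]
) -> MetabolicModel:
    out = model.copy()
    for iv in interventions:
        rxn = out.reaction(iv.reaction_id)
        if iv.kind == "up":
            out.set_bounds(rxn.id, iv.bound, max(rxn.upper_bound, iv.bound))
        elif iv.kind == "down":
            out.set_bounds(rxn.id, min(rxn.lower_bound, iv.bound), iv.bound)
        elif iv.kind == "knockout":
            out.set_bounds(rxn.id, 0.0, 0.0)
        else:
            raise ValueError(f"unknown intervention kind {iv.kind!r}")
    return out


def worst_case_product(
    model: MetabolicModel,
    medium: Optional[Medium],
    product_exchange: str,
    interventions: Sequence[Intervention] = (),
    growth_fraction: float = 0.1,
) -> Optional[float]:
    """Minimum product flux subject to interventions and a growth floor.

    The growth floor is ``growth_fraction`` of the maximum growth *under
    the interventions*.  Returns None when the intervened model cannot
    grow at all (the intervention set is lethal/infeasible).
    """
    trial = _apply_interventions(model, interventions)
    mu_sol = solve_fba(trial, medium=medium)
    if not mu_sol.is_optimal or mu_sol.objective_value <= RANGE_TOL:
        return None
    floor = [LinearConstraint(
        {trial.objective_reaction_id: 1.0},
        lb=growth_fraction * mu_sol.objective_value, ub=None,
        name="growth_floor",
    )]
    lo = optimize_linear(trial, {product_exchange: 1.0}, medium=medium,
                         extra_constraints=floor, sense="min")
    if not lo.is_optimal:
        return None
    return lo.objective_value


def candidate_interventions(
    model: MetabolicModel,
    medium: Optional[Medium],
    must_u: Set[str],
    must_l: Set[str],
    over_ranges: Mapping[str, FluxRange],
    exclude: Optional[Set[str]] = None,
) -> List[Intervention]:
    """Bound interventions implied by MUST membership.

    Up-regulation raises the lower bound to the overproduction-range
    minimum; down-regulation lowers the upper bound to the range maximum
    (a knockout when that maximum is ~0).  Exchange reactions, the
    objective, and anything in ``exclude`` (typically essential
    reactions) are skipped.
    """
    exclude = set(exclude or ())
    exclude |= {r.id for r in model.exchanges}
    exclude.add(model.objective_reaction_id)
    out = []
    for rid in sorted(must_u):
        if rid in exclude or rid not in over_ranges:
            continue
        out.append(Intervention(rid, "up", over_ranges[rid].min_flux))
    for rid in sorted(must_l):
        if rid in exclude or rid not in over_ranges:
            continue
        top = over_ranges[rid].max_flux
        if abs(top) <= RANGE_TOL:
            out.append(Intervention(rid, "knockout", 0.0))
        else:
            out.append(Intervention(rid, "down", top))
    return out


def force_set_search(
    model: MetabolicModel,
    medium: Optional[Medium],
    candidates: Sequence[Intervention],
    product_exchange: str,
    target_product: float,
    max_size: int = 3,
    growth_fraction: float = 0.1,
    tol: float = RANGE_TOL,
) -> ForceSearchResult:
    """Minimal intervention sets guaranteeing the production target.

    Subsets of at most ``max_size`` candidate interventions are
    enumerated; a subset is accepted when its worst-case product (the
    minimum over the remaining flux space, with growth at least
    ``growth_fraction`` of the intervened maximum) meets
    ``target_product``.  Only minimal accepted sets — no accepted proper
    subset — are returned, ordered by size then by guaranteed product
    descending.
    """
    accepted: List[ForceSet] = []
    best = worst_case_product(model, medium, product_exchange, (),
                              growth_fraction) or 0.0
    if max_size >= 1:
        for size in range(1, max_size + 1):
            for combo in itertools.combinations(candidates, size):
                rids = [iv.reaction_id for iv in combo]
                if len(set(rids)) < len(rids):
                    continue
                worst = worst_case_product(
                    model, medium, product_exchange, combo, growth_fraction
                )
                if worst is None:
                    continue
                best = max(best, worst)
                if worst >= target_product - tol:
                    accepted.append(ForceSet(tuple(combo), worst))
    # minimality: drop any set with an accepted proper subset
    accepted_keys = [frozenset(iv.reaction_id for iv in fs.interventions)
                     for fs in accepted]
    minimal = []
    for fs, key in zip(accepted, accepted_keys):
        if not any(other < key for other in accepted_keys):
            minimal.append(fs)
    minimal.sort(key=lambda fs: (len(fs.interventions),
                                 -fs.guaranteed_product))
    return ForceSearchResult(sets=minimal, target_product=target_product,
                             best_worst_case=best)
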