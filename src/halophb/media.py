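"""Nitrogen-normalized media design.

Candidate nitrogen sources (amino acids, ammonium, ...) are compared on a
fair footing by constraining the total nitrogen uptake to a fixed budget:

    sum_i  w_i * |v_EX,i|  =  1 mmol N/(gDCW*h)

where w_i is the number of nitrogen atoms per molecule of source i.  The
absolute value is linearized by restricting every source exchange to
uptake only (flux <= 0), so |v| = -v and the constraint is a plain linear
equality.  The non-growth-associated maintenance (NGAM) lower bound is
set to zero, so the optimal growth rate *is* the maximum theoretical
biomass yield in gDCW per mmol N.  All combinations of up to
``max_sources`` candidates are enumerated, then filtered (sources taking
under 10% of the nitrogen are deemed not significant and dropped),
deduplicated and ranked by yield.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .core import DEFAULT_BOUND, Medium, MetabolicModel, ModelError, parse_formula
from .fba import LinearConstraint, solve_fba

#: Sources taking less than this fraction of total N are filtered out.
MIN_N_FRACTION = 0.10
#: Growth below this is classified as zero_growth.
GROWTH_THRESHOLD = 1e-6


@dataclass(frozen=True)
class NitrogenSource:
    exchange_id: str
    compound_name: str
    w: int  # mol N per mol compound

    def __post_init__(self):
        if self.w < 0:
            raise ValueError(f"{self.compound_name}: negative nitrogen weight")


@dataclass
class MediaCombination:
    sources: Tuple[NitrogenSource, ...]
    status: str  # "optimal", "zero_growth", "infeasible"
    biomass_yield: float = math.nan  # gDCW per mmol N
    n_fraction: Dict[str, float] = field(default_factory=dict)

    @property
    def source_ids(self) -> Tuple[str, ...]:
        return tuple(s.exchange_id for s in self.sources)


@dataclass
class MediaRanking:
    entries: List[MediaCombination]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for combo in self.entries:
            rows.append({
                "combination": "+".join(s.compound_name for s in combo.sources),
                "status": combo.status,
                "biomass_yield": combo.biomass_yield,
                "n_fractions": ";".join(
                    f"{s.compound_name}={combo.n_fraction.get(s.exchange_id, 0.0):.3f}"
                    for s in combo.sources
                ),
            })
        return pd.DataFrame(
            rows, columns=["combination", "status", "biomass_yield", "n_fractions"]
        )


def nitrogen_weight(formula: str) -> int:
    """Number of nitrogen atoms in an elemental formula (w_i of the budget)."""
    return parse_formula(formula).get("N", 0)


def source_from_model(model: MetabolicModel, exchange_id: str,
                      name: Optional[str] = None) -> NitrogenSource:
    """Build a NitrogenSource from an exchange's metabolite formula."""
    rxn = model.reaction(exchange_id)
    if not rxn.is_exchange:
        raise ModelError(f"{exchange_id} is not an exchange reaction")
    met_id = next(iter(rxn.stoichiometry))
    met = model.metabolite(met_id)
    if not met.formula:
        raise ModelError(f"metabolite {met_id} has no formula")
    return NitrogenSource(
        exchange_id=exchange_id,
        compound_name=name or met.name or met_id,
        w=nitrogen_weight(met.formula),
    )


def build_nitrogen_constraint(
    model: MetabolicModel,
    sources: Sequence[NitrogenSource],
    budget: float = 1.0,
) -> LinearConstraint:
    """The nitrogen-budget equality  sum_i w_i * (-v_EX,i) = budget.

    Every source exchange must already be restricted to uptake (upper
    bound <= 0) so that |v| = -v; otherwise an error demands the direction
    restriction.
    """
    coeffs = {}
    for src in sources:
        rxn = model.reaction(src.exchange_id)
        if rxn.upper_bound > 0:
            raise ModelError(
                f"nitrogen source exchange {src.exchange_id} allows secretion "
                f"(upper bound {rxn.upper_bound}); restrict it to uptake first"
            )
        coeffs[src.exchange_id] = -float(src.w)
    return LinearConstraint.equality(coeffs, budget, name="nitrogen_budget")


def _nitrogen_exchanges(model: MetabolicModel) -> List[str]:
    """Exchanges of nitrogen-containing metabolites."""
    out = []
    for rxn in model.exchanges:
        met = model.metabolite(next(iter(rxn.stoichiometry)))
        if met.formula and nitrogen_weight(met.formula) > 0:
            out.append(rxn.id)
    return out


def optimize_media(
    model: MetabolicModel,
    medium_base: Medium,
    candidates: Sequence[NitrogenSource],
    max_sources: int = 3,
    budget: float = 1.0,
    close_ammonium_secretion: bool = True,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> List[MediaCombination]:
    """Evaluate every 1..max_sources combination of nitrogen candidates.

    ``medium_base`` supplies the non-nitrogen exchanges (carbon and oxygen
    should be unbounded for uptake so that nitrogen is the sole
    limitation).  For each combination the NGAM lower bound is zeroed,
    non-member nitrogen exchanges are closed to uptake, member exchanges
    are made uptake-only, the nitrogen budget is imposed, and growth is
    maximized.
    """
    if not candidates:
        raise ValueError("no candidate nitrogen sources")
    base = model.copy()
    if base.ngam_reaction_id:
        ngam = base.reaction(base.ngam_reaction_id)
        base.set_bounds(ngam.id, 0.0, ngam.upper_bound)
    from .core import apply_medium

    base = apply_medium(base, medium_base)
    candidate_ids = {c.exchange_id for c in candidates}
    for ex_id in _nitrogen_exchanges(base):
        rxn = base.reaction(ex_id)
        lb = max(rxn.lower_bound, 0.0)
        ub = rxn.upper_bound
        if close_ammonium_secretion and ex_id in candidate_ids:
            ub = 0.0
        base.set_bounds(ex_id, min(lb, ub), ub)

    results: List[MediaCombination] = []
    for size in range(1, max_sources + 1):
        for combo in itertools.combinations(candidates, size):
            trial = base.copy()
            for src in combo:
                trial.set_bounds(src.exchange_id, -DEFAULT_BOUND, 0.0)
            constraint = build_nitrogen_constraint(trial, combo, budget)
            sol = solve_fba(trial, extra_constraints=[constraint])
            if not sol.is_optimal:
                results.append(MediaCombination(combo, "infeasible"))
                continue
            mu = sol.objective_value
            if mu <= growth_threshold:
                results.append(MediaCombination(combo, "zero_growth",
                                                biomass_yield=0.0))
                continue
            fractions = {
                src.exchange_id:
                    src.w * (-sol.fluxes[src.exchange_id]) / budget
                for src in combo
            }
            results.append(MediaCombination(
                combo, "optimal", biomass_yield=mu / budget,
                n_fraction=fractions,
            ))
    return results


def filter_and_rank(
    results: Sequence[MediaCombination],
    min_fraction: float = MIN_N_FRACTION,
) -> MediaRanking:
    """Drop failures, prune insignificant sources, deduplicate and rank.

    Sources contributing less than ``min_fraction`` of the nitrogen are
    removed and the combination collapses to the remaining sources.
    Duplicates (same reduced source set) keep the best yield.  Ranking is
    by yield descending, ties broken by fewer sources then lexicographic
    exchange ids.
    """
    if not results:
        raise ValueError("no media results to rank")
    reduced: Dict[Tuple[str, ...], MediaCombination] = {}
    for combo in results:
        if combo.status != "optimal":
            continue
        kept = tuple(
            s for s in combo.sources
            if combo.n_fraction.get(s.exchange_id, 0.0) >= min_fraction
        )
        if not kept:
            continue
        total = sum(combo.n_fraction[s.exchange_id] for s in kept)
        fractions = {
            s.exchange_id: combo.n_fraction[s.exchange_id] / total for s in kept
        }
        entry = MediaCombination(
            kept, "optimal", biomass_yield=combo.biomass_yield,
            n_fraction=fractions,
        )
        key = tuple(sorted(s.exchange_id for s in kept))
        incumbent = reduced.get(key)
        if incumbent is None or entry.biomass_yield > incumbent.biomass_yield:
            reduced[key] = entry
    if not reduced:
        warnings.warn("all media combinations filtered out", stacklevel=2)
    ordered = sorted(
        reduced.values(),
        key=lambda c: (-c.biomass_yield, len(c.sources), c.source_ids),
    )
    return MediaRanking(entries=ordered)
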