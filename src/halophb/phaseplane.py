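"""Phenotypic phase planes (PhPP).

Two exchange uptake rates are fixed by equality on a 2-D grid, growth is
maximized in each cell, and the dual values of the two fixing constraints
give the uptake shadow prices.  Regions of constant shadow-price sign
pattern are the metabolic phases; the line of optimality (LO) is the ray
through the origin along which biomass yield on the first substrate is
maximal.

Because the uptakes are *fixed* (not bounded), cells that force more
substrate than the network can dispose of are infeasible; such cells are
retained as data (NaN growth), and forced-overflow cells may legitimately
show negative shadow prices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Medium, MetabolicModel
from .fba import solve_fba_fixed_uptakes

#: Shadow prices below this magnitude are treated as zero when classifying
#: phases (dual degeneracy dead-band).
SHADOW_PRICE_DEADBAND = 1e-6


@dataclass
class PhPPGrid:
    axis1_exchange: str
    axis2_exchange: str
    axis1_rates: np.ndarray  # uptake magnitudes, mmol/(gDCW*h)
    axis2_rates: np.ndarray
    mu: np.ndarray           # growth, 1/h; NaN = infeasible cell
    shadow1: np.ndarray      # d(mu)/d(uptake 1)
    shadow2: np.ndarray
    model_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Long-form export: rate1, rate2, mu, sp1, sp2."""
        rows = []
        for i, r1 in enumerate(self.axis1_rates):
            for j, r2 in enumerate(self.axis2_rates):
                rows.append((r1, r2, self.mu[i, j],
                             self.shadow1[i, j], self.shadow2[i, j]))
        return pd.DataFrame(
            rows, columns=["rate1", "rate2", "mu", "sp1", "sp2"]
        )


@dataclass(frozen=True)
class PhaseRegion:
    label: str
    sign_pattern: Tuple[str, str]  # each of "+", "0", "-" ("?" = infeasible)
    member_cells: frozenset       # of (i, j) grid indices


@dataclass
class LineOfOptimality:
    cells: List[Tuple[int, int]]
    slope: float  # axis2 uptake per axis1 uptake along the fitted ray


def compute_phpp(
    model: MetabolicModel,
    medium: Optional[Medium],
    ex1: str,
    ex2: str,
    n_points: int = 200,
    max_rate: float = 2.0,
    solver: str = "highs",
) -> PhPPGrid:
    """Growth and uptake shadow prices over an equidistant uptake grid.

    Rates run from 0 to ``max_rate`` inclusive (spacing
    ``max_rate/(n_points-1)``).  Infeasible cells are NaN.
    """
    if ex1 == ex2:
        raise ValueError("the two phase-plane exchanges must differ")
    rates = np.linspace(0.0, max_rate, n_points)
    mu = np.full((n_points, n_points), math.nan)
    sp1 = np.full((n_points, n_points), math.nan)
    sp2 = np.full((n_points, n_points), math.nan)
    for i, r1 in enumerate(rates):
        for j, r2 in enumerate(rates):
            sol, prices = solve_fba_fixed_uptakes(
                model, medium, {ex1: r1, ex2: r2}, solver=solver
            )
            if sol.is_optimal:
                mu[i, j] = sol.objective_value
                sp1[i, j] = prices[ex1]
                sp2[i, j] = prices[ex2]
    return PhPPGrid(
        axis1_exchange=ex1, axis2_exchange=ex2,
        axis1_rates=rates, axis2_rates=rates.copy(),
        mu=mu, shadow1=sp1, shadow2=sp2, model_id=model.id,
    )


def _sign(value: float, deadband: float) -> str:
    if math.isnan(value):
        return "?"
    if value > deadband:
        return "+"
    if value < -deadband:
        return "-"
    return "0"


def segment_phases(
    grid: PhPPGrid, deadband: float = SHADOW_PRICE_DEADBAND
) -> List[PhaseRegion]:
    """Connected components of constant shadow-price sign pattern.

    Feasible cells with the same (sign sp1, sign sp2) pattern that touch
    4-connectedly form one phase; all infeasible cells form a single
    region labeled ``infeasible``.  The regions partition the grid.
    """
    n1, n2 = grid.mu.shape
    patterns = np.empty((n1, n2), dtype=object)
    feasible = ~np.isnan(grid.mu)
    for i in range(n1):
        for j in range(n2):
            if not feasible[i, j]:
                patterns[i, j] = ("?", "?")
            else:
                patterns[i, j] = (
                    _sign(grid.shadow1[i, j], deadband),
                    _sign(grid.shadow2[i, j], deadband),
                )
    regions: List[PhaseRegion] = []
    infeasible_cells = frozenset(
        (i, j) for i in range(n1) for j in range(n2) if not feasible[i, j]
    )
    if infeasible_cells:
        regions.append(PhaseRegion("infeasible", ("?", "?"), infeasible_cells))
    unique_patterns = sorted(
        {patterns[i, j] for i in range(n1) for j in range(n2) if feasible[i, j]}
    )
    counter = 0
    for pattern in unique_patterns:
        mask = np.zeros((n1, n2), dtype=bool)
        for i in range(n1):
            for j in range(n2):
                mask[i, j] = feasible[i, j] and patterns[i, j] == pattern
        labels, n_comp = ndimage.label(mask)
        for comp in range(1, n_comp + 1):
            counter += 1
            cells = frozenset(map(tuple, np.argwhere(labels == comp)))
            regions.append(PhaseRegion(
                label=f"P{counter}({pattern[0]},{pattern[1]})",
                sign_pattern=pattern,
                member_cells=cells,
            ))
    return regions


def line_of_optimality(grid: PhPPGrid, rel_tol: float = 1e-6) -> LineOfOptimality:
    """Cells maximizing biomass yield on substrate 1, fitted as a ray.

    For each positive axis-1 rate the axis-2 rate attaining the maximal
    mu/rate1 ratio with the least substrate use is selected; a ray through
    the origin is least-squares fitted to the selected cells.
    """
    cells: List[Tuple[int, int]] = []
    for i, r1 in enumerate(grid.axis1_rates):
        if r1 <= 0:
            continue
        col = grid.mu[i, :]
        feasible = ~np.isnan(col)
        if not feasible.any():
            continue
        yields = np.where(feasible, col / r1, -math.inf)
        best = yields.max()
        if best <= 0:
            continue
        candidates = np.nonzero(yields >= best * (1 - rel_tol))[0]
        cells.append((i, int(candidates.min())))
    if not cells:
        raise ValueError("no growing cells in the grid; cannot place the LO")
    x = np.array([grid.axis1_rates[i] for i, _ in cells])
    y = np.array([grid.axis2_rates[j] for _, j in cells])
    slope = float(np.dot(x, y) / np.dot(x, x))
    return LineOfOptimality(cells=cells, slope=slope)


@dataclass(frozen=True)
class PointPlacement:
    rate1: float
    rate2: float
    in_range: bool
    phase_label: str
    shadow_prices: Tuple[float, float]
    cell: Optional[Tuple[int, int]]


def locate_points(
    grid: PhPPGrid,
    regions: Sequence[PhaseRegion],
    points: Sequence[Tuple[float, float]],
) -> List[PointPlacement]:
    """Place experimental uptake points on the computed phase plane.

    Each point is snapped to the nearest grid cell and labeled with the
    containing phase and the cell's shadow prices.  Out-of-range points
    are flagged but still reported.
    """
    cell_to_region: Dict[Tuple[int, int], str] = {}
    for region in regions:
        for cell in region.member_cells:
            cell_to_region[cell] = region.label
    placements = []
    lo1, hi1 = grid.axis1_rates[0], grid.axis1_rates[-1]
    lo2, hi2 = grid.axis2_rates[0], grid.axis2_rates[-1]
    for r1, r2 in points:
        in_range = (lo1 <= r1 <= hi1) and (lo2 <= r2 <= hi2)
        i = int(np.argmin(np.abs(grid.axis1_rates - r1)))
        j = int(np.argmin(np.abs(grid.axis2_rates - r2)))
        placements.append(PointPlacement(
            rate1=r1, rate2=r2, in_range=in_range,
            phase_label=cell_to_region.get((i, j), "unknown"),
            shadow_prices=(grid.shadow1[i, j], grid.shadow2[i, j]),
            cell=(i, j),
        ))
    return placements


def distance_to_lo(lo: LineOfOptimality, rate1: float, rate2: float) -> float:
    """Euclidean distance from an uptake point to the fitted LO ray."""
    # Ray direction (1, slope) normalized; distance = |cross product|.
    norm = math.hypot(1.0, lo.slope)
    return abs(rate2 - lo.slope * rate1) / norm
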