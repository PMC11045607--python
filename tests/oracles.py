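"""Independent oracles used by the test suite.

These deliberately avoid the package's LP/GPR code paths: FBA optima are
recomputed by exhaustive vertex enumeration of the flux polytope, GPR
evaluation by brute-force set logic on the rule string, and essentiality
by explicit reaction removal.
"""

from __future__ import annotations

import itertools
import math
import re
from typing import Optional

import numpy as np


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-8) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} (finite bounds).

    A vertex has at least n - rank(S) variables at a bound with the
    remaining columns independent; every such active set is enumerated
    and the square system solved.  Exponential, for tiny networks only.
    """
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    n_fixed = n - rank
    vertices = []
    for fixed_idx in itertools.combinations(range(n), n_fixed):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        if free_idx and np.linalg.matrix_rank(A) < len(free_idx):
            continue
        for pattern in itertools.product((0, 1), repeat=n_fixed):
            v = np.empty(n)
            for j, p in zip(fixed_idx, pattern):
                v[j] = lb[j] if p == 0 else ub[j]
            b = -S[:, list(fixed_idx)] @ v[list(fixed_idx)] if n_fixed else \
                np.zeros(m)
            if free_idx:
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free_idx] = sol
            if np.max(np.abs(S @ v)) > tol * max(1.0, np.abs(v).max()):
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            vertices.append(np.clip(v, lb, ub))
    if not vertices:
        return np.empty((0, n))
    return np.array(vertices)


def brute_force_lp(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                   c: np.ndarray) -> Optional[float]:
    """max c'v over the flux polytope via vertex enumeration (None if empty)."""
    verts = enumerate_vertices(S, lb, ub)
    if verts.shape[0] == 0:
        return None
    return float(np.max(verts @ c))


def brute_force_fba(model) -> Optional[float]:
    """Vertex-enumeration optimum of a MetabolicModel's objective."""
    S = model.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.objective_reaction_id)] = 1.0
    return brute_force_lp(S, lb, ub, c)


# ---------------------------------------------------------------------------
# GPR truth tables
# ---------------------------------------------------------------------------

def gpr_truth_eval(rule: str, active_genes: set) -> bool:
    """Evaluate a GPR rule string with Python's own boolean evaluator."""
    if not rule.strip():
        return True
    tokens = re.findall(r"\(|\)|[A-Za-z0-9_.\-]+", rule)
    python_expr = []
    for tok in tokens:
        if tok in ("(", ")"):
            python_expr.append(tok)
        elif tok.lower() in ("and", "or"):
            python_expr.append(tok.lower())
        else:
            python_expr.append("True" if tok in active_genes else "False")
    return bool(eval(" ".join(python_expr)))  # noqa: S307 - test oracle


# ---------------------------------------------------------------------------
# Essentiality by explicit reaction removal
# ---------------------------------------------------------------------------

def essentiality_by_reaction_removal(model, medium, gene: str,
                                     solve_fba) -> float:
    """Knockout growth obtained by removing the GPR-inactivated reactions
    computed with the truth-table oracle (not the package's GPR tree)."""
    ko = model.copy()
    all_genes = set(model.genes)
    active = all_genes - {gene}
    for rxn in ko.reactions:
        rule = rxn.gpr.to_string()
        if not gpr_truth_eval(rule, active):
            ko.set_bounds(rxn.id, 0.0, 0.0)
    sol = solve_fba(ko, medium=medium)
    return sol.objective_value if sol.is_optimal else 0.0


def finite_difference_shadow_price(model, medium, exchange_id: str,
                                   rate: float, solve_fixed,
                                   h: float = 1e-5) -> float:
    """Central finite-difference d(mu)/d(uptake) at a fixed uptake point."""
    sol_hi, _ = solve_fixed(model, medium, {exchange_id: rate + h})
    sol_lo, _ = solve_fixed(model, medium, {exchange_id: rate - h})
    if not (sol_hi.is_optimal and sol_lo.is_optimal):
        return math.nan
    return (sol_hi.objective_value - sol_lo.objective_value) / (2 * h)
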