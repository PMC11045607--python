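"""Synthetic data generators.

Three generators support desk-scale verification of every analysis in the
package:

* :func:`build_mini_halo` — "mini-Halo", a deliberately small metabolic
  model of an aerobic, PHB-accumulating halophile with lumped central
  carbon metabolism, dual nitrogen assimilation (direct glutamate uptake
  and ammonium via a lumped GS/GOGAT step), a three-enzyme PHB pathway
  (beta-ketothiolase PhaA, acetoacetyl-CoA reductase PhaB, PHB synthase
  PhaC) and a biomass reaction with growth-associated (GAM) and separate
  non-growth-associated (NGAM) maintenance.  All coefficients are small
  rationals so the optimal yields below can be re-derived by hand.

* :func:`random_small_network` — random stoichiometric networks small
  enough for exhaustive vertex-enumeration oracles.

* :func:`simulate_batch` — a biphasic batch fermentation (lag, growth
  phase A on the first nitrogen source, phase B on the second) with
  multiplicative log-normal measurement noise.

Analytic optima of mini-Halo (derivation in docs/methods.md)
------------------------------------------------------------
Per unit growth the biomass equation drains 0.5 glutamate, 1.2 acetyl-CoA,
0.2 lipid (made from 4 acetyl-CoA each), 2 NADPH and 10 ATP, so 2.0
acetyl-CoA and 10.4 ATP per unit growth in total.  Catabolism yields 2
acetyl-CoA, 12 ATP and 4 NADPH per glucose.  Hence with NGAM = 0:

* nitrogen-limited growth:  mu = 2 * (glutamate uptake)   [0.5 N per unit]
* carbon-limited growth:    mu = 1 * (glucose uptake)
* biomass yield per mmol N: 2.0 (identical for glutamate and ammonium,
  because either route delivers one glutamate per nitrogen and carbon is
  in excess)
* PHB: one C4 residue per glucose, i.e. 86.09/180.156 = 0.4779 g PHB per
  g glucose regardless of the polymer chain configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    DEFAULT_BOUND,
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    add_polymer_reaction,
    molar_mass,
)
from .kinetics import TimeCourse

# -- documented analytic constants for the default mini-Halo ---------------
#: Default medium: glucose, glutamate and oxygen uptake, mmol/(gDCW*h).
DEFAULT_MEDIUM: Medium = {
    "EX_glc": (-10.0, 0.0),
    "EX_glu": (-2.0, 0.0),
    "EX_o2": (-20.0, 0.0),
}
#: Glucose + ammonium medium (no glutamate).
AMMONIUM_MEDIUM: Medium = {
    "EX_glc": (-10.0, 0.0),
    "EX_nh4": (-2.0, 0.0),
    "EX_o2": (-20.0, 0.0),
}
#: Max growth on DEFAULT_MEDIUM: nitrogen-limited, 2 * 2.0 mmol glutamate.
MINI_HALO_MU_MAX = 4.0
#: Biomass yield per mmol nitrogen (glutamate or ammonium), gDCW/mmol N.
YIELD_X_PER_N = 2.0
#: Biomass yield per mmol glucose under carbon limitation.
YIELD_X_PER_GLC = 1.0
#: Mass yield of PHB on glucose, g/g (86.09 / 180.156).
PHB_MASS_YIELD_PER_GLC = molar_mass("C4H6O2") / molar_mass("C6H12O6")
#: Nitrogen-to-carbon uptake ratio along the line of optimality
#: (glutamate uptake / glucose uptake at maximal biomass yield).
LO_SLOPE_GLU_PER_GLC = 0.5


@dataclass(frozen=True)
class ToyModelSpec:
    """Configuration of the mini-Halo generator."""

    include_phb: bool = True
    n_assimilation: str = "both"  # "glutamate", "ammonium" or "both"
    residues_per_monomer: int = 4
    monomers_per_polymer: int = 4000
    gam_atp: float = 5.0       # mmol ATP per gDCW, growth-associated
    base_atp: float = 5.0      # non-maintenance ATP drain of biomass
    ngam_rate: float = 0.0     # default lower bound of the NGAM reaction
    biomass_glutamate: float = 0.5
    biomass_accoa: float = 1.2
    biomass_lipid: float = 0.2
    biomass_nadph: float = 2.0


def build_mini_halo(spec: Optional[ToyModelSpec] = None) -> MetabolicModel:
    """Deterministic small GEM of a PHB-accumulating halophile."""
    if spec is None:
        spec = ToyModelSpec()
    if spec.n_assimilation not in ("glutamate", "ammonium", "both"):
        raise ValueError(f"unknown n_assimilation {spec.n_assimilation!r}")
    with_glu = spec.n_assimilation in ("glutamate", "both")
    with_nh4 = spec.n_assimilation in ("ammonium", "both")

    mets = [
        Metabolite("glc_e", "D-glucose", "e", "C6H12O6"),
        Metabolite("glc_c", "D-glucose", "c", "C6H12O6"),
        Metabolite("nh4_e", "ammonium", "e", "H4N", 1),
        Metabolite("nh4_c", "ammonium", "c", "H4N", 1),
        Metabolite("o2_e", "oxygen", "e", "O2"),
        Metabolite("o2_c", "oxygen", "c", "O2"),
        Metabolite("co2_e", "carbon dioxide", "e", "CO2"),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2"),
        Metabolite("glu_e", "L-glutamate", "e", "C5H9NO4"),
        Metabolite("glu_c", "L-glutamate", "c", "C5H9NO4"),
        Metabolite("arg_e", "L-arginine", "e", "C6H14N4O2"),
        Metabolite("arg_c", "L-arginine", "c", "C6H14N4O2"),
        Metabolite("accoa_c", "acetyl-CoA (lumped)", "c"),
        Metabolite("atp_c", "ATP (lumped phosphorylation potential)", "c"),
        Metabolite("nadph_c", "NADPH (lumped redox)", "c"),
        Metabolite("lipid_c", "membrane lipid (lumped)", "c"),
    ]
    rxns = [
        # exchanges: closed to uptake by default, secretion open
        Reaction("EX_glc", {"glc_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="exchange"),
        Reaction("EX_glu", {"glu_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="exchange"),
        Reaction("EX_nh4", {"nh4_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="exchange"),
        Reaction("EX_o2", {"o2_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="exchange"),
        Reaction("EX_co2", {"co2_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="exchange"),
        Reaction("EX_arg", {"arg_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="exchange"),
        # transport
        Reaction("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, DEFAULT_BOUND,
                 gpr="glcT", subsystem="transport"),
        Reaction("NH4t", {"nh4_e": -1.0, "nh4_c": 1.0}, -DEFAULT_BOUND,
                 DEFAULT_BOUND, gpr="amtB", subsystem="transport"),
        Reaction("O2t", {"o2_e": -1.0, "o2_c": 1.0}, 0.0, DEFAULT_BOUND,
                 subsystem="transport"),
        Reaction("CO2t", {"co2_c": -1.0, "co2_e": 1.0}, 0.0, DEFAULT_BOUND,
                 subsystem="transport"),
        Reaction("ARGt", {"arg_e": -1.0, "arg_c": 1.0}, 0.0, DEFAULT_BOUND,
                 gpr="artP", subsystem="transport"),
        # arginine is imported but not catabolized: it accumulates as an
        # osmolyte (sink), so its nitrogen is unavailable for growth
        Reaction("ARGACC", {"arg_c": -1.0}, 0.0, DEFAULT_BOUND,
                 subsystem="osmolyte accumulation"),
        # lumped glycolysis + TCA + oxidative phosphorylation
        Reaction(
            "GLYC_TCA",
            {"glc_c": -1.0, "o2_c": -2.0, "accoa_c": 2.0, "co2_c": 2.0,
             "atp_c": 12.0, "nadph_c": 4.0},
            0.0, DEFAULT_BOUND, gpr="glk1 or glk2",
            subsystem="central carbon metabolism",
        ),
        # complete oxidation of acetyl-CoA (overflow of excess carbon)
        Reaction(
            "ACOAOX",
            {"accoa_c": -1.0, "o2_c": -2.0, "co2_c": 2.0, "atp_c": 10.0},
            0.0, DEFAULT_BOUND, gpr="acsOx",
            subsystem="central carbon metabolism",
        ),
        # NADPH re-oxidation (transhydrogenase-like sink)
        Reaction(
            "NADPHOX", {"nadph_c": -1.0, "o2_c": -0.5}, 0.0, DEFAULT_BOUND,
            gpr="sthA", subsystem="central carbon metabolism",
        ),
        # fatty-acid synthesis: the acetyl-CoA drain into membrane lipids
        Reaction(
            "FAS",
            {"accoa_c": -4.0, "atp_c": -2.0, "nadph_c": -4.0, "lipid_c": 1.0},
            0.0, DEFAULT_BOUND, gpr="fabF", subsystem="lipid metabolism",
        ),
        # glutamate disposal (oxidative degradation; no energy recovered)
        Reaction(
            "GLUDEG", {"glu_c": -1.0, "nh4_c": 1.0, "co2_c": 5.0},
            0.0, DEFAULT_BOUND, gpr="gdhA", subsystem="nitrogen metabolism",
        ),
        # maintenance ATP hydrolysis (NGAM); upper bound also drains excess ATP
        Reaction("NGAM", {"atp_c": -1.0}, spec.ngam_rate, DEFAULT_BOUND,
                 subsystem="maintenance"),
    ]
    if with_glu:
        rxns.append(Reaction("GLUt", {"glu_e": -1.0, "glu_c": 1.0}, 0.0,
                             DEFAULT_BOUND, gpr="gltP", subsystem="transport"))
    if with_nh4:
        # lumped GS/GOGAT: ammonium fixed onto a C4 skeleton at ATP+NADPH cost
        rxns.append(Reaction(
            "GS_GOGAT",
            {"nh4_c": -1.0, "accoa_c": -2.0, "atp_c": -1.0, "nadph_c": -1.0,
             "glu_c": 1.0},
            0.0, DEFAULT_BOUND, gpr="glnA and gltB",
            subsystem="nitrogen metabolism",
        ))
    atp_total = spec.base_atp + spec.gam_atp
    rxns.append(Reaction(
        "BIOMASS",
        {"glu_c": -spec.biomass_glutamate, "accoa_c": -spec.biomass_accoa,
         "lipid_c": -spec.biomass_lipid, "nadph_c": -spec.biomass_nadph,
         "atp_c": -atp_total},
        0.0, DEFAULT_BOUND, subsystem="biomass",
    ))
    model = MetabolicModel(
        id="mini_halo",
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id="BIOMASS",
        ngam_reaction_id="NGAM",
    )
    if spec.include_phb:
        model.add_metabolite(
            Metabolite("phb_c", "3-hydroxybutyrate residue", "c", "C4H6O2")
        )
        model.add_metabolite(Metabolite("aacoa_c", "acetoacetyl-CoA", "c"))
        model.add_metabolite(Metabolite("hbcoa_c", "3-hydroxybutyryl-CoA", "c"))
        model.add_reaction(Reaction(
            "PHAA", {"accoa_c": -2.0, "aacoa_c": 1.0}, 0.0, DEFAULT_BOUND,
            gpr="phaA", subsystem="PHB synthesis",
        ))
        model.add_reaction(Reaction(
            "PHAB", {"aacoa_c": -1.0, "nadph_c": -1.0, "hbcoa_c": 1.0},
            0.0, DEFAULT_BOUND, gpr="phaB", subsystem="PHB synthesis",
        ))
        model.add_reaction(Reaction(
            "PHAC", {"hbcoa_c": -1.0, "phb_c": 1.0}, 0.0, DEFAULT_BOUND,
            gpr="phaC", subsystem="PHB synthesis",
        ))
        model = add_polymer_reaction(
            model, "phb_c",
            residues_per_monomer=spec.residues_per_monomer,
            monomers_per_polymer=spec.monomers_per_polymer,
        )
    model.validate()
    return model


def random_small_network(
    n_mets: int, n_rxns: int, seed: int
) -> MetabolicModel:
    """Random stoichiometric network for LP oracle sweeps.

    Bounds are finite and always admit the zero flux vector, so the LP
    feasible set is a non-empty bounded polytope whose optimum a
    vertex-enumeration oracle can find exhaustively.  Deterministic per
    seed; intended for n_rxns <= 8.
    """
    rng = np.random.default_rng(seed)
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        k = int(rng.integers(1, min(3, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        stoich = {f"m{int(i)}": float(c) for i, c in zip(chosen, coeffs)}
        lb = float(rng.choice([0.0, -5.0, -10.0], p=[0.4, 0.4, 0.2]))
        ub = float(rng.choice([5.0, 10.0]))
        rxns.append(Reaction(f"r{j}", stoich, lb, ub))
    objective = f"r{n_rxns - 1}"
    model = MetabolicModel(
        id=f"random_{seed}", metabolites=mets, reactions=rxns,
        objective_reaction_id=objective,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Batch fermentation simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FermentationParams:
    """Biphasic aerobic batch culture on glucose + two nitrogen sources.

    Phase A runs on the primary nitrogen source (glutamate) until its
    depletion, phase B on ammonium; growth stops when ammonium runs out.
    Default rates mirror an aerobic glutamate-medium fermentation of a
    halophile: mu_A = 0.073 1/h, mu_B = 0.042 1/h, glutamate uptake
    -1.169, ammonium production +0.123 (phase A) and uptake -0.116
    (phase B), glucose uptake -0.782 / -0.630 mmol/(gDCW*h).
    """

    mu_A: float = 0.073
    mu_B: float = 0.042
    lag: float = 9.0            # h
    t_end: float = 72.0         # h
    dt: float = 2.0             # sampling interval, h
    X0: float = 0.1             # gDCW/L
    glucose_0: float = 40.0     # mmol/L
    glutamate_0: float = 5.8    # mmol/L
    ammonium_0: float = 2.6     # mmol/L
    r_glc_A: float = -0.782     # mmol/(gDCW*h)
    r_glc_B: float = -0.630
    r_glu_A: float = -1.169
    r_nh4_A: float = 0.123
    r_nh4_B: float = -0.116
    noise_sd: float = 0.05      # multiplicative log-normal sigma
    detection_limit: float = 0.01
    seed: int = 0


@dataclass
class BatchTruth:
    """Noise-free parameters and phase boundaries of a simulated batch."""

    params: FermentationParams
    t_lag_end: float
    t_phase_a_end: float
    t_n_depleted: Optional[float]


@dataclass
class SimulatedBatch:
    timecourse: TimeCourse
    truth: BatchTruth


def _phase_a_end(p: FermentationParams) -> float:
    """Time at which the primary nitrogen source is exhausted."""
    # glu(t) = glu0 - (|r|/mu) (X(t) - X0), X(t) = X0 exp(mu (t - lag))
    dx = p.glutamate_0 * p.mu_A / abs(p.r_glu_A)
    return p.lag + math.log(1.0 + dx / p.X0) / p.mu_A


def simulate_batch(params: Optional[FermentationParams] = None) -> SimulatedBatch:
    """Piecewise-exponential biphasic batch culture with measurement noise.

    Concentration trajectories are linked to biomass by constant specific
    rates (dS/dX = r/mu within each phase), sampled on a regular grid and
    perturbed by multiplicative log-normal noise with a detection-limit
    floor.  The noise-free truth is returned alongside the data.
    """
    p = params or FermentationParams()
    if min(p.mu_A, p.mu_B, p.lag, p.dt, p.X0) < 0:
        raise ValueError("rates, lag, dt and X0 must be non-negative")
    t = np.arange(0.0, p.t_end + 1e-9, p.dt)
    t_dep = _phase_a_end(p)
    x_dep = p.X0 * math.exp(p.mu_A * (t_dep - p.lag))
    nh4_dep = p.ammonium_0 + (p.r_nh4_A / p.mu_A) * (x_dep - p.X0)

    # ammonium depletion during phase B, if it occurs before t_end
    t_n_dep: Optional[float] = None
    if p.r_nh4_B < 0:
        dx_b = nh4_dep * p.mu_B / abs(p.r_nh4_B)
        t_cand = t_dep + math.log(1.0 + dx_b / x_dep) / p.mu_B
        if t_cand < p.t_end:
            t_n_dep = t_cand
    x_final = (
        x_dep * math.exp(p.mu_B * (t_n_dep - t_dep)) if t_n_dep else None
    )

    def biomass_at(ti: float) -> float:
        if ti <= p.lag:
            return p.X0
        if ti <= t_dep:
            return p.X0 * math.exp(p.mu_A * (ti - p.lag))
        if t_n_dep is None or ti <= t_n_dep:
            return x_dep * math.exp(p.mu_B * (ti - t_dep))
        return x_final

    X = np.array([biomass_at(ti) for ti in t])

    def conc(s0: float, r_a: float, r_b: float) -> np.ndarray:
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            xi = X[i]
            if ti <= t_dep:
                val = s0 + (r_a / p.mu_A) * (xi - p.X0)
            else:
                s_dep = s0 + (r_a / p.mu_A) * (x_dep - p.X0)
                val = s_dep + (r_b / p.mu_B) * (xi - x_dep)
            out[i] = max(val, 0.0)
        return out

    glc = conc(p.glucose_0, p.r_glc_A, p.r_glc_B)
    glu = conc(p.glutamate_0, p.r_glu_A, 0.0)
    nh4 = conc(p.ammonium_0, p.r_nh4_A, p.r_nh4_B)

    rng = np.random.default_rng(p.seed)

    def noisy(values: np.ndarray) -> np.ndarray:
        if p.noise_sd == 0:
            return values.copy()
        factors = np.exp(p.noise_sd * rng.standard_normal(values.shape))
        return np.maximum(values * factors, p.detection_limit)

    tc = TimeCourse(
        time=t,
        biomass=noisy(X),
        metabolites={
            "glucose": noisy(glc),
            "glutamate": noisy(glu),
            "ammonium": noisy(nh4),
        },
        replicate_id=f"sim_seed{p.seed}",
    )
    truth = BatchTruth(
        params=p, t_lag_end=p.lag, t_phase_a_end=t_dep, t_n_depleted=t_n_dep
    )
    return SimulatedBatch(timecourse=tc, truth=truth)
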