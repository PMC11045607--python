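# Methods

## The constraint-based model

A metabolic network is represented by its stoichiometric matrix S
(metabolites × reactions).  At steady state, flux balance analysis (FBA)
solves

    max  c'v    s.t.   S v = 0,   lb ≤ v ≤ ub,

with the biomass reaction as objective (flux in 1/h; all other fluxes in
mmol/(gDCW·h)).  Exchange reactions are single-metabolite boundary
reactions with uptake negative.  `apply_medium` replaces the bounds of
listed exchanges and closes the *uptake* direction of every unlisted
exchange, leaving secretion open — an organism may excrete products that
are not part of the medium definition.

The LP backend is HiGHS through `scipy.optimize.linprog`, requested at
1e-9 feasibility/optimality tolerances because the downstream phase-
plane work consumes dual values.  All duals are reported on the
maximization scale (scipy's marginals refer to the minimized objective
and are negated).  Flux variability analysis (FVA) re-optimizes each
reaction in both senses under an objective floor `c'v ≥ f·opt`.
Degenerate optima are possible at phase boundaries; dual values are
taken from the solver's returned basis and consumers apply a dead-band
(|π| < 1e-6 → 0) before interpreting signs.

Gene-protein-reaction (GPR) rules are boolean trees over gene ids
(`and` = complex, `or` = isozymes, case-insensitive; empty rule = the
reaction survives any deletion).  A gene deletion disables every
reaction whose rule evaluates false; essentiality compares knockout FBA
growth with wild type (essential below 1% of wild type, growth-reducing
below 99%, otherwise non-essential; both cutoffs configurable — the
1%/99% defaults are conventional).

## Phenotypic phase planes

Both uptake rates are fixed **by equality** on an equidistant grid
(default 200 points from 0 to 2 mmol/(gDCW·h), endpoints included), and
growth is maximized per cell.  The dual of each fixing constraint is the
uptake shadow price, converted so that positive means "more uptake
raises growth".  Because the uptakes are fixed rather than bounded,
cells that force more substrate than the network can dispose of are
infeasible, and forced-overflow cells can carry negative prices; both
are retained as data.  Phases are 4-connected components of constant
shadow-price sign pattern; infeasible cells form their own region.  The
line of optimality (LO) selects, for each first-substrate rate, the
second-substrate rate attaining the maximal biomass yield µ/rate₁ with
the least substrate use, and fits a ray through the origin to the
selected cells by least squares.

## Nitrogen-normalized media design

Candidate nitrogen sources are compared at a fixed nitrogen budget

    Σᵢ wᵢ · |v_EX,i| = 1 mmol N/(gDCW·h),

with wᵢ the nitrogen atom count of the compound (arginine 4, ammonium
1).  The absolute value is linearized by restricting source exchanges to
uptake only; the constraint is then a plain linear equality and the
whole problem stays an LP.  Non-member nitrogen exchanges are closed to
uptake, ammonium secretion is closed during optimization (otherwise the
budget is gameable by futile uptake/secretion cycles; configurable), and
the NGAM lower bound is set to zero so that, by LP homogeneity, the
optimal growth rate equals the maximum theoretical biomass yield in gDCW
per mmol N and scales exactly linearly with the budget.  All 1..3-source
combinations are enumerated; sources taking under 10% of the consumed
nitrogen are deemed insignificant, combinations collapse to their
significant sources, duplicates keep the best yield, and ranking is by
yield descending with ties broken by fewer sources then lexicographic
ids.

## Batch kinetics

The specific growth rate is the OLS slope of ln(biomass) versus time
within an exponential window; lag-phase data are excluded.  Yields are
OLS slopes of metabolite concentration versus biomass concentration
(dS/dX, mmol/gDCW), and specific rates follow from r = µ·(dS/dX) = µ/Y
with Y = dX/dS, uptake negative.  Standard errors propagate to first
order.  Phase splitting uses a marker metabolite (the first nitrogen
source): the lag ends at the first sample whose decline below the
initial level (median of the first three samples) exceeds twice the
measurement SD and persists; phase A ends at the last sample before the
marker reads below its depletion threshold (default 2% of the initial
concentration — the choice is a convention); phase B covers the rest.
Boundary samples are assigned away from the fitted windows because a
flat lag point or a detection-limit-clamped depletion point biases the
log-linear fits.

## Biomass equation refinement

The biomass equation is a map of precursor drains (mmol/gDCW) plus a
growth-associated maintenance ATP term (GAM).  Between two reference
equations measured at different salinities, coefficients interpolate
linearly in the salt concentration (no extrapolation).  GAM is fitted to
an observed growth rate at equality-fixed measured uptakes by monotone
bisection — growth is non-increasing in GAM because every unit of
biomass costs more ATP, and strictly decreasing while ATP is the binding
resource, so the solution is unique.  Coefficient refinement minimizes
the mean relative yield error over observed conditions with a small
genetic algorithm: population 50, 100 generations, tournament selection
(size 3), uniform crossover, Gaussian mutation with σ = 5% of the search
range, elitism 1, coefficients bounded to [0.1×, 10×] their initial
values, fully deterministic given the seed.  Elitism guarantees the
refined error never exceeds the initial error.  Only the k most
sensitive coefficients are optimized, ranked by central finite
differences of the mean predicted yield (k is exposed because which
components dominate depends on the limitation pattern of the data).

## OptForce-style strain design

Wild-type flux ranges come from FVA with growth at ≥ 99% of its maximum
(the wild-type reference is configurable); overproduction ranges from
per-reaction min/max under "product ≥ target fraction × theoretical
maximum" with growth free.  A reaction whose overproduction range lies
strictly above (below) its wild-type range joins MUST-U (MUST-L);
second-order sets classify sums and differences of candidate pairs the
same way.  Candidate pairs are shortlisted by flux coupling analysis on
the directionality-preserving flux cone: for each ordered pair two LPs
bound the ratio vᵢ/vⱼ with vⱼ normalized to 1, giving full / partial /
directional / uncoupled classes.

The original bilevel MILP is replaced by exhaustive subset enumeration:
interventions are derived from MUST membership (up-regulation raises the
lower bound to the overproduction-range minimum, down-regulation lowers
the upper bound to the range maximum, a knockout when that maximum is
~0; exchanges, the objective and essential reactions are excluded), and
every subset of at most three interventions is certified by a
worst-case inner LP that *minimizes* product formation subject to the
interventions and growth ≥ 10% (configurable) of the post-intervention
maximum.  On candidate lists of this size the guarantee is identical to
the bilevel formulation and needs no MILP solver.  Only minimal accepted
sets are returned.

## The mini-Halo toy model

`build_mini_halo` emulates, at desk scale, an aerobic halophilic
PHB producer growing on glucose with glutamate and/or ammonium as
nitrogen sources: lumped glycolysis+TCA+oxidative phosphorylation
(1 glucose + 2 O₂ → 2 acetyl-CoA + 2 CO₂ + 12 ATP + 4 NADPH), complete
acetyl-CoA oxidation and an NADPH oxidase as overflow valves, direct
glutamate uptake and a lumped GS/GOGAT ammonium assimilation
(1 NH₄ + 2 acetyl-CoA + ATP + NADPH → glutamate), oxidative glutamate
disposal, a fatty-acid drain into membrane lipids (4 acetyl-CoA +
2 ATP + 4 NADPH per lipid), the three-step PHB pathway
(PhaA: 2 acetyl-CoA → acetoacetyl-CoA; PhaB: +NADPH →
3-hydroxybutyryl-CoA; PhaC: → C4 residue), the polymer builder (default
4 residues per short-chain monomer, 4000 monomers per polymer), an
arginine transporter whose cargo only accumulates as an osmolyte (an
importable but unassimilable nitrogen source), and a biomass reaction
draining 0.5 glutamate, 1.2 acetyl-CoA, 0.2 lipid, 2 NADPH and
(5 base + 5 GAM) ATP per unit growth, with a separate NGAM reaction
(default lower bound 0 so that yields are homogeneous; tests that probe
maintenance set it explicitly).

All coefficients are small rationals so the optima are hand-checkable:

* total acetyl-CoA demand per unit growth = 1.2 + 4·0.2 = 2.0, supplied
  at 2 per glucose → carbon-limited growth µ = u_glc;
* one glutamate carries one nitrogen and biomass needs 0.5 → nitrogen-
  limited growth µ = 2·u_N for glutamate *and* ammonium (carbon, ATP and
  NADPH in excess), hence the biomass yield of 2.0 gDCW per mmol N and
  the equality of the two nitrogen sources by construction;
* with O₂ unlimited, µ(u_glc, u_glu) = min(u_glc, 2·u_glu), so the phase
  plane has exactly a carbon-limited phase (shadow prices (1, 0)), a
  nitrogen-limited phase ((0, 2)) and LO slope u_glu/u_glc = 1/2;
* PHB: one C4 residue (2 acetyl-CoA, 1 NADPH) per glucose → mass yield
  86.09/180.156 = 0.4779 g/g, invariant to the polymer chain
  configuration because polymerization is a pure rescaling;
* with glucose fixed at 1 and nitrogen in excess, ATP becomes binding
  above GAM ≈ 6.6 with closed form µ = 32/(25.4 + GAM), used to verify
  the GAM fit.

On the default medium (glucose −10, glutamate −2, O₂ −20) growth is
nitrogen-limited at µ = 4.0.  Forced-uptake analyses use an O₂-unbounded
medium because disposing of forced excess carbon costs oxygen.

## The batch-fermentation simulator

`simulate_batch` produces a biphasic aerobic batch culture: constant
biomass through the lag (default 9 h), exponential growth at µ_A on the
primary nitrogen source until its depletion (≈ 30 h with the default
inoculum and substrate levels), then µ_B on ammonium until that runs out
(≈ 60 h), then stationary.  Metabolite trajectories are tied to biomass
by constant specific rates (dS/dX = r/µ per phase); the default rates
(µ_A = 0.073, µ_B = 0.042 1/h; glutamate −1.169, glucose −0.782/−0.630,
ammonium +0.123/−0.116 mmol/(gDCW·h)) describe a glutamate-medium
fermentation of a halophile, including ammonium *production* during
phase A and its consumption in phase B.  Noise is multiplicative
log-normal (default σ = 0.05) with a 0.01 detection-limit floor, applied
to biomass and concentrations alike; the noise-free truth and phase
boundaries are returned alongside.  Default sampling is every 2 h over
72 h; the two-standard-error coverage study samples hourly so each phase
holds ~20 points and the OLS slope interval is calibrated.  The
simulator generates data only — it performs no Monod/ODE inference, and
real fermentations differ from it in ways passing tests cannot probe:
substrate-dependent (non-constant) specific rates, CO₂/O₂ transfer
limitations, autocorrelated sensor drift, and sampling-volume effects.

## Numerical conventions and limitations

* LP tolerances 1e-9; FVA/coupling classification tolerance 1e-6;
  shadow-price dead-band 1e-6; growth threshold 1e-6 1/h.
* The vertex-enumeration oracle used in the tests is exponential and
  restricted to networks of ≤ 8 reactions with finite bounds.
* Flux coupling is computed on the flux cone with directionality from
  the medium-constrained bounds; magnitudes of the original bounds do
  not enter the classification.
* JSON model round-trips are bit-exact; SBML round-trips preserve
  numeric fields to double precision but not the NGAM designation
  (JSON-dialect only).
* `random_small_network` guarantees the zero flux vector is feasible,
  so generated LPs are never infeasible — empty-polytope behavior is
  covered by directed tests instead.
* The GA is a simple elitist implementation intended for ≤ ~5 refined
  coefficients; high-dimensional refinement would need a proper
  optimizer.
* Problem sizes in the shipped analyses (50×50 phase-plane grids, 500
  kinetics replicates, GA with population 40 × 80 generations in the
  recovery study) were chosen so the full pipeline re-runs in about a
  minute on a laptop while keeping every statistical margin comfortable.
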