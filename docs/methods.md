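# Methods

This note documents the model as implemented: its assumptions, parameters,
numerical choices, the reduced-scale experiment protocol, and what the
simulations do and do not demonstrate.

## Model and assumptions

The simulator couples four components on a shared node-centered lattice
(0.05 mm spacing, physical position = index × spacing, node (0,0,0) at the
domain corner):

1. **Molecular transport.**  Ten nondimensional concentration fields evolve
   by advection–diffusion–reaction with a transvascular source.  Metabolites
   and growth factors are normalized by their characteristic concentrations;
   the drugs by the MTD injection dose.  ECM is matrix-bound (no transport);
   all other species are advected by the interstitial flow, retarded by
   r_f = 0.9.  The vascular exchange of a species is
   P_eff·(S/V)·(c_plasma − c) plus solvent drag (1−σ_f)·J_v⁺·c_plasma,
   applied at nodes crossed by perfused segments.  VEGF fenestrates the wall:
   P_eff and the hydraulic conductivity L_p rise saturably with the local
   VEGF signal.
2. **Cell physiology.**  Vitality aggregates oxygen (with an additive Warburg
   constant k_W), glucose, and a quartic CO₂ penalty active only above the
   characteristic CO₂ level; both Heaviside switches use H(0) = 1 and cell
   activity is the single strict test υ > υ^ch, so boundary cases fall
   deterministically on the quiescent side.  Energy integrates ATP
   production (linear in υ, active cells only) against Michaelis–Menten
   consumption (M-M constant 1) and a drug term with maximum rate k_ac·c_ac.
   Phenotypes move only along stroma→proliferative (division),
   proliferative↔quiescent, quiescent→necrotic; necrosis is absorbing.
3. **Lattice agents.**  Tumor cells and endothelial tip cells move to
   6-connected neighbors with probabilities assembled from the standard
   hybrid discretization of their continuum density equations: motility
   D·dt/h² plus 0.5·(coefficient)·(field difference) per neighbor, clipped at
   zero, divided by a solid-pressure factor 1/(1 + k_sp·max(0, ρ_live −
   ρ_th)), and excluded at necrotic or out-of-domain nodes.  Daughters may
   displace viable (never necrotic) cells outward along the division
   direction, at most 5 deep; displaced cells carry their energy unchanged.
   Division probability falls linearly with the live 6-neighborhood density
   and is zero at the cap.  Update order is re-randomized each step from the
   run RNG.
4. **Vasculature and fluid.**  The mother vessel is a circle of diameter
   0.8× the smaller planar extent, discretized to lattice nodes in the mid-z
   plane, with Dirichlet inlet/outlet pressures (25/10 mmHg) at opposite
   points.  Sprout initiation and wall branching share one probability law,
   saturating in VEGF (half level 0.1) and in the ang-2:ang-1 ratio; stalk
   death is threshold-linear below a critical VEGF support.  Anastomosis
   requires node coincidence.  Segment flow is Poiseuille; radii relax toward
   a target wall shear (0.04 mmHg ≈ 5 Pa) at gain 0.5/day within
   [2, 12] µm; segments whose surrounding live density exceeds 0.8 collapse
   (zero conductance, geometry kept); the mother vessel is exempt.  A segment
   is flagged perfused iff both endpoints reach the inlet *and* outlet
   through conducting segments.  Interstitial pressure solves the
   quasi-steady Darcy equation with Starling sources, lymphatic drainage
   only outside the tumor region, and p_i = 0 on the faces; velocity is
   −K∇p_i.  The tumor region for spatial averages is the morphological
   closure of the viable+necrotic mask.

The model deliberately omits immune cells, fibroblasts, pharmacodynamic
dependence of the kill term on hypoxia or quiescence, vessel regression in
response to reduced metabolic demand, and poroelastic tissue deformation
(solid stress acts only as migration resistance and vessel compression).

## Anti-VEGF action

The anti-angiogenic drug attenuates the VEGF signal as
c_v/(1 + k·c_ag), with three separate gains reflecting three distinct wall
responses:

* `k_ag_signal` (0.10) for endothelial decisions (tip selection, branching,
  stalk survival and proliferation) — prevents new, immature vessels;
* `k_ag_lp` (1.0) for wall hydraulic conductivity — restores the fluid
  barrier, preserving transvascular pressure differences and lowering tumor
  IFP (vascular normalization);
* `k_ag_solute` (0.03) for solute exchange — normalization largely spares
  small-solute (nutrient, drug) delivery through the existing wall area.

A single shared gain either starved the tumor outright (anti-angiogenic arms
dominating every cytotoxic schedule) or abolished the IFP response; the split
encodes that an anti-VEGF antibody tightens endothelial junctions long before
it blocks small-molecule diffusion.  Metronomic chemotherapy normalizes
vessels by two indirect routes that emerge in simulation: the sustained drug
level suppresses endothelial proliferation (extension stalls whenever local
c_ac exceeds 5% of the MTD peak), and the relieved hypoxia lowers VEGF
production, which is proportional to the oxygen deficit
max(0, 1 − c_o2/c_o2^ch) — so treated, well-oxygenated tumors become less
leaky, not just less vascularized.

## Parameters

All constants live in `src/tmesim/data/parameters.yaml` with units of mm,
day and mmHg, and a provenance tag per value: `literature` (drug half-lives
30 min and 20 days, dose fractions, plasma viscosity, tissue and wall
hydraulic conductivities), `reconstructed` (the 14-day MTD interval and the
mother-vessel diameter fraction), or `fallback` (everything the sources do
not pin down — diffusivities, reaction rates, taxis weights, thresholds —
chosen once to make the model's qualitative behaviors hold and frozen).
Any value can be overridden with `--set key=value` for sensitivity sweeps.

Parameters that matter most: the characteristic drug concentration
`c_ac_ch = 0.001` sets drug potency (the energy equation sees
c_ac/c_ac_ch, i.e. a tissue level of 0.1% of the MTD dose has unit effect);
`k_ap = 2/day`, `k_ac = 1/day` give well-fed cells a division time near one
day; `k_qc = 3/day` necroses a deeply quiescent cell in about two days;
oxygen uptake 50/day against D = 0.3 mm²/day sets an oxygen penetration
length of ~0.08 mm, producing hypoxic cores at sub-millimeter tumor radii.
Diffusivities are effective model values on the simulation's day timescale,
not molecular free diffusivities: they are chosen so reaction–diffusion
penetration lengths (the quantity that shapes the morphology) are realistic
while the explicit scheme remains affordable.

## Numerics

Explicit forward Euler with operator splitting (advection → diffusion →
reaction/source).  The substep is bounded by min_i h²/(6 D_i) and the
advective CFL (safety 0.9), recomputed each cellular step from the current
velocity field.  Advection is first-order conservative upwind with zero
boundary-face flux; diffusion uses the 7-point Laplacian with mirror ghosts
(second-order no-flux at the nodes), which conserves the trapezoidal mass
functional exactly — mass accounting therefore uses trapezoidal quadrature.
Negative concentrations after the reaction step are clamped to zero and the
clamped mass is accumulated per species for audit (≤0.1% of field mass per
step in the shipped presets).  The Darcy operator is SPD and solved by
conjugate gradients to 1e−8 relative residual; network pressures by a sparse
direct solve.  Cellular updates use one step per `dt_cell_days` (0.05 day)
with the molecular substeps nested inside.  A run is a pure function of
(config, seed): a single NumPy Generator drives every stochastic choice in a
fixed iteration order, and checkpoints capture the full state, so resumed
runs are bit-identical.

## Presets and the reduced-scale experiment

`full` is the published geometry and protocol: 10×10×8 mm on 201×201×161
nodes, untreated growth to day 36 (tumor diameter ~4 mm), then treatment to
day 78.  Running it takes hours (`scripts/full_scale_check.py`); the test
suite exercises its configuration and pipeline wiring only.

`desk` (41×41×33 nodes, 2×2×1.6 mm) keeps the full spacing and runs its
3-day untreated course in ~90 s on one CPU.  `unit` (9×9×9) serves
operation-level tests.

`mini` (17×17×13 nodes, 0.8×0.8×0.6 mm) is the package's experiment preset:
2.5 days of untreated growth from a 0.12 mm seed (by which point the tumor
is vascularized and has a hypoxic core), then 8 days of treatment.  The
regimen comparison grows one tumor per seed, clones the grown state, and
runs every regimen from the identical clone with the same RNG stream, so
differences are attributable to treatment.  Orderings are asserted on
paired-seed means: individual seeds can (and occasionally do) swap the
neighboring M and AA+MTD arms.  Tumor IFP is compared as its time average
over the treatment window, since the instantaneous end-point value is
dominated by where in the dose cycle the run happens to stop.

At this scale the MTD arm receives a single bolus inside the window (its
next dose falls 14 days later), so the metronomic advantage appears as
sustained suppression versus post-bolus regrowth, and the fold ratios
between arms are compressed relative to a 42-day treatment course; their
*ordering* — MTD > AA+MTD > M > AA+M in end-point viable cells, and
MTD highest in window-averaged tumor IFP with both anti-VEGF arms lowest —
is the scale-robust observable.

## What passing tests show, and what they do not

The simulations start from a programmatic seed tumor and an idealized
circular mother vessel; no biological data are consumed.  Passing tests
demonstrate internal correctness (closed-form and dense-oracle agreement of
the transport, flow and PK kernels; state-machine and conservation
invariants) and that the implemented mechanisms reproduce the qualitative
treatment phenomenology at reduced scale.  They do not calibrate the model
to any tumor type: absolute cell counts, IFP magnitudes (small at
sub-millimeter scale, since IFP scales with the vascularized tumor radius)
and fold ratios are scale- and parameter-dependent.  Real tumors add immune
and stromal interactions, pharmacodynamic complexity and vessel regression
that the model intentionally leaves out.

## Degenerate inputs and tie-breaks

Grids require ≥2 nodes and positive extent per axis.  υ = υ^ch classifies
as quiescent; c_co2 = c_co2^ch incurs zero penalty (continuous).  A division
with no admissible direction aborts and is logged, not an error.  An
all-necrotic lattice steps as a no-op.  Vessel networks with a disconnected
inlet/outlet raise a solver error naming the condition; NaN/Inf in any field
aborts with the species and step index.  Empty-tumor spatial metrics raise
(`hypoxic_ratio`) or return empty/zero (`find_clusters`, `mean_tumor_ifp`)
per their contracts; the drug delivery factor is reported missing once no
live cells remain.
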