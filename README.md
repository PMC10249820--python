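# tmesim

A multi-scale, three-dimensional simulator of vascularized tumor growth and
treatment scheduling, built for exploring why *how* a cytotoxic drug is
scheduled — one large bolus at the maximum tolerated dose (MTD) versus
frequent low "metronomic" doses — changes tumor control, and how
anti-angiogenic (anti-VEGF) co-treatment reshapes the answer through
vascular normalization.  It is aimed at computational-biology researchers
studying transport barriers in the tumor microenvironment: drug delivery,
interstitial fluid pressure (IFP), hypoxia and cancer-cell invasion.

## The model

Three coupled scales on one lattice (node spacing 0.05 mm):

**Molecular.**  Ten species c_i — anti-cancer drug *ac*, anti-angiogenic
agent *ag*, glucose *g*, oxygen *o2*, CO₂, VEGF *v*, angiopoietin-1/2,
MMPs *m* and ECM *e* — obey advection–diffusion–reaction transport

```
∂c_i/∂t + ∇·(r_f u_ins c_i) = D_i ∇²c_i + R_i + S_i
```

with interstitial-fluid advection (retardation r_f), cellular
consumption/production R_i, and transvascular Starling exchange S_i at
perfused-vessel nodes, solved by explicit finite differences (first-order
upwind advection, 7-point Laplacian, no-flux boundaries).

**Cellular.**  Each tumor cell carries a vitality υ and an ATP-like energy ψ:

```
υ = φ (c_o2/(c_o2+c_o2^ch) + k_W) · c_g/(c_g+c_g^ch) · exp(−5 (c_co2/c_co2^ch − 1)⁴ H(c_co2 − c_co2^ch))

dψ/dt = (k_ap υ − k_ac υ/(υ+1) − k_ac c_ac υ/(υ+1)) H(υ − υ^ch) − k_qc υ/(υ+1) H(υ^ch − υ)
```

Cells with υ > υ^ch are proliferative and divide once ψ reaches ψ^ch;
below-threshold cells are quiescent, and a quiescent cell whose energy is
exhausted becomes necrotic (absorbing).  The anti-cancer drug enters the
energy balance as a Michaelis–Menten consumption with maximum rate
k_ac·c_ac, so sustained exposure arrests proliferation while brief spikes
are partly wasted — the kinetic heart of the MTD-versus-metronomic contrast.

**Tissue.**  Tumor cells and endothelial tip cells migrate as lattice agents
with move probabilities discretized from

```
∂ρ_tEC/∂t = D_tEC ∇²ρ_tEC − ∇·( β_c/(1+α c_v) ρ_tEC ∇c_v + β_h ρ_tEC ∇c_e )
∂ρ_TC/∂t  = D_TC  ∇²ρ_TC  − ∇·( β_h ρ_TC ∇c_e + β_cop ρ_TC ∇υ )
```

(saturable VEGF chemotaxis, ECM haptotaxis, vessel cooption along ∇υ, solid
pressure resisting migration; necrotic regions are impenetrable).  Sprouts
initiate and branch from an idealized circular mother vessel in the mid-z
plane with a probability rising in VEGF and the ang-2:ang-1 ratio; stalk-cell
proliferation extends sprouts and is killed by the anti-cancer drug — the
indirect normalization mechanism of metronomic scheduling.  Segment flows are
Poiseuille/Kirchhoff solves; radii adapt to wall shear; crowded segments
collapse.  Interstitial pressure obeys quasi-steady Darcy flow with Starling
sources and normal-tissue-only lymphatics, and u_ins = −K∇p_i.

**Treatment.**  Plasma drug curves are exact superpositions of decaying
boluses (cisplatin half-life 30 min; anti-VEGF antibody 20 days).  Regimens:
`mtd` (dose 1.0 every 14 days), `m` (0.2 daily), `aa+mtd`, `aa+m`, `none`.

## Worked example

Grow an untreated tumor for 2.5 simulated days on the compact `mini` preset
(17×17×13 nodes, 0.8×0.8×0.6 mm) and write metrics, VTK snapshots and a
reproducibility manifest:

```bash
tmesim simulate --preset mini --seed 1 --days 2.5 --out demo
```

The run prints its manifest (`"config_hash": "d546c2429d2221f0", "seed": 1,
...`) and `demo/metrics.csv` ends with

```
time_days,proliferative,quiescent,necrotic,viable,total,hypoxic_ratio,...,mean_tumor_ifp,...
2.0,113,0,3,113,116,0.586,...,0.0274,...
2.5,128,0,3,128,131,0.366,...,0.0324,...
```

read: by day 2.5 the 57-cell seed has grown to 131 cells, 3 of them necrotic
at the oxygen-starved core; 37% of tumor nodes are hypoxic (oxygen below half
its characteristic level) and the mean tumor IFP has risen to 0.03 mmHg as
leaky angiogenic sprouts reach the tumor.  Re-running with the same seed
reproduces the file bit-for-bit.

Treatment comparisons start every regimen from the same grown tumor:

```bash
tmesim compare --preset mini --seeds 1,2 --out compare.csv
```

which reports end-point viable-cell fold ratios relative to the AA+M
combination, ordered MTD > AA+MTD > M > AA+M as in the underlying model
study.  The `desk` preset (41×41×33 nodes, 2×2×1.6 mm) runs its untreated
3-day course in ~90 s on one CPU; the `full` preset is the published
10×10×8 mm, 78-day protocol and takes hours
(`python scripts/full_scale_check.py`).

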