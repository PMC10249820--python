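"""Advection-diffusion-reaction transport of the ten molecular species.

Each species ``i`` obeys

    dc_i/dt + div(r_f * u_ins * c_i) = D_i lap(c_i) + R_i + S_i

with interstitial-fluid advection (retarded by ``r_f``), Fickian diffusion, a
net reaction term ``R_i`` (cellular consumption/production, decay, matrix
degradation) and a transvascular source ``S_i`` (Starling-type exchange with
the plasma at perfused-vessel nodes).

Species: ``ac`` anti-cancer drug, ``ag`` anti-angiogenic agent, ``g`` glucose,
``o2`` oxygen, ``co2`` carbon dioxide, ``v`` VEGF, ``a1``/``a2``
angiopoietin-1/2, ``m`` MMPs, ``e`` ECM (fibronectin; matrix-bound, neither
advected nor diffused).  All fields are nondimensional (metabolites by their
characteristic concentrations, drugs by the MTD injection dose).

Numerics: explicit forward Euler with operator splitting (advection ->
diffusion -> reaction/source); first-order conservative upwind advection;
7-point Laplacian with no-flux (reflecting) boundaries.  The stable time step
is ``min_i h^2 / (6 D_i)`` combined with the advective CFL bound.  Negative
values arising from the reaction step are clamped to zero and the clamped
mass is accounted per species for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPECIES = ("ac", "ag", "g", "o2", "co2", "v", "a1", "a2", "m", "e")

#: species that are advected by interstitial flow (ECM is matrix-bound)
ADVECTED = {s: s != "e" for s in SPECIES}


class NumericalError(RuntimeError):
    """NaN/Inf detected in a field during time stepping."""


@dataclass
class ScalarFieldSet:
    """One 3D nondimensional concentration field per species."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    data: dict[str, np.ndarray] = field(default_factory=dict)
    clamped_mass: dict[str, float] = field(default_factory=dict)
    last_clamped_mass: dict[str, float] = field(default_factory=dict)

    @classmethod
    def initial(cls, grid, ecm: float = 1.0, o2: float = 1.0, g: float = 1.0):
        """Normal-tissue initial condition: nutrients at their characteristic
        level, intact ECM, everything else zero."""
        fs = cls(tuple(grid.shape), tuple(grid.spacing_mm))
        for s in SPECIES:
            fs.data[s] = np.zeros(grid.shape, dtype=float)
            fs.clamped_mass[s] = 0.0
            fs.last_clamped_mass[s] = 0.0
        fs.data["e"][:] = ecm
        fs.data["o2"][:] = o2
        fs.data["g"][:] = g
        return fs

    def __getitem__(self, species: str) -> np.ndarray:
        return self.data[species]

    def total_mass(self, species: str) -> float:
        """Trapezoidal-quadrature mass (boundary nodes carry half weight),
        the discrete functional the no-flux diffusion stencil conserves."""
        h = self.spacing
        c = self.data[species]
        w = c.copy()
        for axis in range(3):
            sl0, sl1 = [slice(None)] * 3, [slice(None)] * 3
            sl0[axis], sl1[axis] = 0, -1
            w[tuple(sl0)] *= 0.5
            w[tuple(sl1)] *= 0.5
        return float(w.sum()) * h[0] * h[1] * h[2]

    def check_finite(self, step: int | None = None) -> None:
        for s, arr in self.data.items():
            if not np.all(np.isfinite(arr)):
                where = "" if step is None else f" at step {step}"
                raise NumericalError(f"non-finite values in species {s!r}{where}")


@dataclass
class ReactionContext:
    """Pure-function inputs for reaction and vascular-exchange terms.

    The orchestrator assembles this from the cell lattice, the vessel network
    and the treatment schedules; reaction terms depend on nothing else.
    """

    params: object
    live_mask: np.ndarray            # proliferative | quiescent tumor cells
    necrotic_mask: np.ndarray
    tip_mask: np.ndarray             # tip-endothelial agent positions
    vessel_mask: np.ndarray          # nodes crossed by perfused segments
    area_density: np.ndarray         # vessel surface area per tissue volume, 1/mm
    plasma: dict[str, float]         # plasma concentration per exchanged species
    transvascular_flux: np.ndarray | None = None   # Jv per node, 1/day
    flow_solved: bool = False

    def effective_permeability(self, species: str, c_v: np.ndarray,
                               c_ag: np.ndarray) -> np.ndarray:
        """Solute wall permeability (mm/day), amplified by VEGF-driven wall
        fenestration.  The anti-VEGF drug restores the *fluid* barrier (see
        the hydraulic conductivity in the flow module) and halts endothelial
        proliferation, but exchanged solute delivery through the existing
        wall area is largely preserved -- vascular normalization mostly spares
        small-solute delivery (weak attenuation ``k_ag_solute``)."""
        p = self.params
        base = p.P_antibody if species == "ag" else p.P_small_solute
        v_sol = c_v / (1.0 + p.k_ag_solute * c_ag)
        sat = v_sol / (v_sol + p.vegf_perm_half)
        return base * (1.0 + p.k_P_vegf * sat)


def laplacian(c: np.ndarray, spacing) -> np.ndarray:
    """7-point Laplacian with mirror (no-flux) boundaries.

    The ghost value across a boundary node mirrors its interior neighbor
    (c[-1] = c[1]), which is second-order accurate for a zero normal
    derivative at the node and conserves the trapezoidal mass exactly.
    """
    out = np.zeros_like(c)
    for axis, h in enumerate(spacing):
        padded = np.concatenate(
            (np.take(c, [1], axis=axis), c, np.take(c, [-2], axis=axis)), axis=axis
        )
        n = c.shape[axis]
        plus = np.take(padded, range(2, n + 2), axis=axis)
        minus = np.take(padded, range(0, n), axis=axis)
        out += (plus - 2.0 * c + minus) / h**2
    return out


def upwind_advection(c: np.ndarray, velocity, spacing, r_f: float) -> np.ndarray:
    """-div(r_f u c) by first-order conservative upwind fluxes.

    ``velocity`` is a tuple of three node-centered arrays (mm/day).  Face
    velocities are averaged from the nodes; boundary faces carry zero flux, so
    the scheme conserves mass exactly on the closed domain.
    """
    out = np.zeros_like(c)
    for axis in range(3):
        u = velocity[axis]
        h = spacing[axis]
        # interior face velocity between node i and i+1 along axis
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        u_face = 0.5 * (u[tuple(sl_lo)] + u[tuple(sl_hi)]) * r_f
        donor = np.where(u_face > 0.0, c[tuple(sl_lo)], c[tuple(sl_hi)])
        flux = u_face * donor                      # per unit area
        # divergence: outflow through +face minus inflow through -face
        grow = np.zeros_like(c)
        grow[tuple(sl_lo)] -= flux / h
        grow[tuple(sl_hi)] += flux / h
        out += grow
    return out


def stable_dt(spacing, params, velocity=None, safety: float = 0.9) -> float:
    """Largest stable forward-Euler step (days) for diffusion + advection."""
    h2 = min(h**2 for h in spacing)
    d_max = max(params[f"D_{s}"] for s in SPECIES)
    dt = h2 / (6.0 * max(d_max, 1e-30))
    if velocity is not None:
        umax = sum(float(np.max(np.abs(v))) for v in velocity)
        if umax > 0:
            dt = min(dt, min(spacing) / umax)
    return safety * dt


def reaction_terms(context: ReactionContext, species: str,
                   fields: ScalarFieldSet) -> np.ndarray:
    """Net volumetric reaction rate R_i (per day) for one species."""
    p = context.params
    live = context.live_mask.astype(float)
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}")

    if species == "o2":
        c = fields["o2"]
        return -p.k_o2_uptake * live * c / (c + p.k_mm_conc)
    if species == "g":
        c = fields["g"]
        return -p.k_g_uptake * live * c / (c + p.k_mm_conc)
    if species == "co2":
        o2 = fields["o2"]
        g = fields["g"]
        return live * (
            p.co2_yield * p.k_o2_uptake * o2 / (o2 + p.k_mm_conc)
            + p.co2_glyc_yield * p.k_g_uptake * g / (g + p.k_mm_conc)
        )
    if species == "v":
        # production switches on below the characteristic oxygen level and
        # deepens with the hypoxia severity
        deficit = np.maximum(0.0, 1.0 - fields["o2"] / p.c_o2_ch)
        prod = p.k_v_production * live * deficit
        bind = p.k_v_binding * context.vessel_mask.astype(float) * fields["v"]
        return prod - bind - p.k_v_decay * fields["v"]
    if species == "a1":
        prod = p.k_a1_production * context.vessel_mask.astype(float)
        return prod - p.k_ang_decay * fields["a1"]
    if species == "a2":
        hypoxic = (fields["o2"] < p.c_o2_ch).astype(float)
        return p.k_a2_production * hypoxic - p.k_ang_decay * fields["a2"]
    if species == "m":
        makers = np.logical_or(context.live_mask, context.tip_mask).astype(float)
        return p.k_m_production * makers - p.k_m_decay * fields["m"]
    if species == "e":
        return -p.k_e_degradation * fields["m"] * fields["e"]
    if species == "ac":
        lam = np.log(2.0) / p.ac_half_life_days
        return -lam * fields["ac"]
    if species == "ag":
        lam = np.log(2.0) / p.ag_half_life_days
        return -lam * fields["ag"]
    raise KeyError(species)


def vascular_exchange(context: ReactionContext, species: str,
                      fields: ScalarFieldSet) -> np.ndarray:
    """Transvascular source S_i (per day): diffusive wall exchange plus
    solvent drag, at perfused-vessel nodes only."""
    if not context.flow_solved:
        raise RuntimeError("vascular_exchange requires a solved flow state")
    if species not in context.plasma:
        return np.zeros(fields.shape)
    p = context.params
    c_pl = context.plasma[species]
    c = fields[species]
    perm = context.effective_permeability(species, fields["v"], fields["ag"])
    s = perm * context.area_density * (c_pl - c)
    if context.transvascular_flux is not None:
        jv_in = np.maximum(context.transvascular_flux, 0.0)
        s = s + (1.0 - p.sigma_filtration) * jv_in * c_pl
    return s * context.vessel_mask


def step_species(fields: ScalarFieldSet, velocity, context: ReactionContext,
                 dt: float, step: int | None = None) -> ScalarFieldSet:
    """Advance every species one split step: advection -> diffusion ->
    reaction/source.  Negative values are clamped with mass accounting."""
    p = context.params
    h = fields.spacing
    cell_vol = h[0] * h[1] * h[2]
    for s in SPECIES:
        c = fields.data[s]
        if velocity is not None and ADVECTED[s]:
            c = c + dt * upwind_advection(c, velocity, h, p.retardation_factor)
        D = p[f"D_{s}"]
        if D > 0.0:
            c = c + dt * D * laplacian(c, h)
        rate = reaction_terms(context, s, fields)
        if context.flow_solved:
            rate = rate + vascular_exchange(context, s, fields)
        c = c + dt * rate
        neg = np.minimum(c, 0.0)
        clamped = -float(neg.sum()) * cell_vol
        fields.last_clamped_mass[s] = clamped
        fields.clamped_mass[s] += clamped
        fields.data[s] = np.maximum(c, 0.0)
    fields.check_finite(step)
    return fields
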