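"""Cellular-scale physiology: vitality, energy, phenotypes, endothelial states.

Tumor cells carry two scalar states.  *Vitality* (upsilon) is an instantaneous
metabolic fitness computed from the local oxygen, glucose and CO2 levels:

    upsilon = phi * (c_o2/(c_o2 + c_o2^ch) + k_W) * c_g/(c_g + c_g^ch)
              * exp(-5 * (c_co2/c_co2^ch - 1)^4 * H(c_co2 - c_co2^ch))

The additive Warburg constant ``k_W`` lets glycolytic metabolism sustain some
vitality without oxygen; the quartic exponential penalizes CO2 accumulation
above its characteristic level.  *Energy* (psi) is an ATP-like reserve
integrated in time:

    dpsi/dt = (k_ap u - k_ac u/(u+1) - k_ac c_ac u/(u+1)) H(u - u^ch)
              - k_qc u/(u+1) H(u^ch - u)

Active cells (upsilon above the characteristic vitality) produce ATP linearly
in vitality and consume it by Michaelis-Menten kinetics (M-M constant 1); the
anti-cancer drug adds an M-M consumption with maximum rate ``k_ac * c_ac``.
Quiescent cells only consume.  A cell divides once psi reaches psi^ch;
a quiescent cell whose psi hits zero becomes necrotic, an absorbing state.

Both Heaviside uses share H(0) = 1, and activity is the single strict switch
``upsilon > upsilon^ch``: ties fall on the quiescent side, which is the same
branch H selects at upsilon = upsilon^ch.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Phenotype", "ECRole", "EndothelialState", "vitality", "step_energy",
    "update_phenotype", "update_endothelial", "StateMachineError",
]


class StateMachineError(RuntimeError):
    """A forbidden phenotype/state transition was requested."""


class Phenotype(IntEnum):
    """Lattice phenotype labels (also the VTK export labels)."""

    STROMA = 0          # normal tissue / empty of tumor cells
    PROLIFERATIVE = 1   # active tumor cell (vitality above threshold)
    QUIESCENT = 2
    NECROTIC = 3


class ECRole(IntEnum):
    STALK = 0
    TIP = 1
    DEAD = 2


def vitality(c_o2, c_g, c_co2, params):
    """Cellular vitality from local metabolite levels.  Accepts arrays."""
    c_o2 = np.asarray(c_o2, dtype=float)
    c_g = np.asarray(c_g, dtype=float)
    c_co2 = np.asarray(c_co2, dtype=float)
    if np.any(c_o2 < 0) or np.any(c_g < 0) or np.any(c_co2 < 0):
        raise ValueError("concentrations must be non-negative")
    oxy = c_o2 / (c_o2 + params.c_o2_ch) + params.k_W
    glc = c_g / (c_g + params.c_g_ch)
    x = c_co2 / params.c_co2_ch - 1.0
    heav = np.where(x >= 0.0, 1.0, 0.0)          # H(0) = 1
    pen = np.exp(-5.0 * x**4 * heav)
    out = params.phi * oxy * glc * pen
    return out if out.ndim else float(out)


def energy_rate(psi, upsilon, c_ac, params):
    """Right-hand side of the energy balance.  ``c_ac`` is the anti-cancer
    drug level already scaled by its characteristic concentration."""
    psi = np.asarray(psi, dtype=float)
    upsilon = np.asarray(upsilon, dtype=float)
    c_ac = np.asarray(c_ac, dtype=float)
    if np.any(psi < 0) or np.any(upsilon < 0) or np.any(c_ac < 0):
        raise ValueError("psi, vitality and drug level must be non-negative")
    mm = upsilon / (upsilon + 1.0)
    active = upsilon > params.vitality_ch       # strict: ties are quiescent-side
    gain = params.k_ap * upsilon - params.k_ac * mm - params.k_ac * c_ac * mm
    drain = -params.k_qc * mm
    rate = np.where(active, gain, drain)
    return rate if rate.ndim else float(rate)


def step_energy(psi, upsilon, c_ac, dt, params):
    """One forward-Euler energy step, clamped at zero."""
    new = np.asarray(psi, dtype=float) + dt * energy_rate(psi, upsilon, c_ac, params)
    new = np.maximum(new, 0.0)
    return new if new.ndim else float(new)


def update_phenotype(current: Phenotype, upsilon: float, psi: float, params) -> Phenotype:
    """Phenotype transition for one live tumor cell.

    active (proliferative) iff upsilon > upsilon^ch; otherwise quiescent while
    psi > 0 and necrotic once a quiescent cell's energy is exhausted.
    Necrotic is absorbing and must not be passed in.
    """
    if current == Phenotype.NECROTIC:
        raise StateMachineError("update_phenotype called on a necrotic cell")
    if current == Phenotype.STROMA:
        raise StateMachineError("update_phenotype called on an empty node")
    if upsilon > params.vitality_ch:
        return Phenotype.PROLIFERATIVE
    if psi > 0.0 or current == Phenotype.PROLIFERATIVE:
        # a starved active cell passes through quiescence before necrosis
        return Phenotype.QUIESCENT
    return Phenotype.NECROTIC


def division_eligible(phenotype: Phenotype, psi: float, params) -> bool:
    return phenotype == Phenotype.PROLIFERATIVE and psi >= params.energy_ch


@dataclass
class EndothelialState:
    """State of the endothelial cells on one vessel segment wall."""

    role: ECRole = ECRole.STALK
    proliferation_eligible: bool = True


def effective_vegf(c_v: float, c_ag: float, params) -> float:
    """VEGF signal after anti-VEGF attenuation: c_v / (1 + k * c_ag)."""
    return c_v / (1.0 + params.k_ag_signal * c_ag)


def update_endothelial(state: EndothelialState, c_v: float, c_a1: float,
                       c_a2: float, c_ac: float, c_ag: float,
                       params) -> EndothelialState:
    """Advance one stalk-cell state from its local molecular readings.

    * death when the (anti-VEGF-attenuated) VEGF support falls below the
      survival threshold -- the caller draws against ``sec_death_rate``;
      here we mark the deterministic part: zero support kills outright;
    * tip selection when both VEGF and the ang-2:ang-1 ratio are high;
    * proliferation suppressed by anti-cancer drug above the endothelial
      kill threshold (the metronomic normalization mechanism) or when the
      effective VEGF signal is too low.
    """
    if state.role == ECRole.DEAD:
        raise StateMachineError("update_endothelial called on a dead EC")
    v_eff = effective_vegf(c_v, c_ag, params)
    if v_eff <= 0.0:
        return EndothelialState(ECRole.DEAD, False)
    role = state.role
    ratio = c_a2 / c_a1 if c_a1 > 0 else np.inf
    if (role == ECRole.STALK and v_eff >= params.tip_vegf_threshold
            and ratio >= params.tip_ang_ratio_threshold):
        role = ECRole.TIP
    prolif = (
        c_ac <= params.ec_drug_kill_threshold
        and v_eff >= params.ec_proliferation_vegf_min
    )
    return EndothelialState(role, prolif)


def sec_death_probability(c_v: float, c_ag: float, dt: float, params) -> float:
    """Threshold-linear stalk-cell death law: the per-step death probability
    rises linearly as the effective VEGF falls below its critical level."""
    v_eff = effective_vegf(c_v, c_ag, params)
    crit = params.sec_death_vegf_critical
    if v_eff >= crit:
        return 0.0
    return min(1.0, params.sec_death_rate * (1.0 - v_eff / crit) * dt)
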