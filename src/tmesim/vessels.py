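"""Sprouting-angiogenesis vessel network on the tissue lattice.

The vasculature is a graph whose nodes are lattice indices and whose edges
are vessel segments with radius, length and flow attributes.  At t = 0 the
only vessel is an idealized circular "mother vessel" in the mid-z plane,
with fixed-pressure inlet and outlet at diametrically opposite points.

Angiogenic sprouts are led by tip-cell agents performing a biased random
walk: random motility plus saturable chemotaxis up the VEGF gradient
(coefficient ``beta_c / (1 + alpha c_v)``) and haptotaxis up the ECM
gradient, blocked by necrotic regions and resisted by solid pressure.
Sprout extension requires the trailing stalk cells to be
proliferation-eligible (suppressed by the anti-cancer drug above the
endothelial kill threshold, or by anti-VEGF signal attenuation -- the
mechanism of chemotherapy-induced vascular normalization).  Tips that step
onto an existing vessel anastomose with it and retire; closed loops that
connect the inlet to the outlet become perfused.

Wall stalk cells convert to new tips (branching) with a probability that
saturates in VEGF and in the ang-2:ang-1 ratio.  Perfused segments adapt
their radius toward a target wall shear stress, and segments compressed by
high local live-cell density collapse to zero flow (geometry retained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cells import ECRole, EndothelialState, Phenotype, effective_vegf, \
    sec_death_probability, update_endothelial
from .tumor import DIRECTIONS, CellLattice, MoveProbabilities, _normalize, move_weights


@dataclass
class TipCell:
    """Agent leading one angiogenic sprout."""

    position: tuple[int, int, int]
    age: int = 0
    idle_age: int = 0
    active: bool = True


class VesselNetwork:
    """Graph of vessel segments plus tip-cell agents."""

    def __init__(self, grid, params):
        self.grid = grid
        self.params = params
        self.graph = nx.Graph()
        self.tips: list[TipCell] = []
        self.segments_created = 0
        self.inlet: tuple | None = None
        self.outlet: tuple | None = None
        self._build_mother_vessel()

    # -- construction -----------------------------------------------------
    def _build_mother_vessel(self) -> None:
        g = self.grid
        h = g.spacing_mm
        nx_, ny, nz = g.shape
        cx = (nx_ - 1) / 2.0
        cy = (ny - 1) / 2.0
        kz = (nz - 1) // 2                      # mid-z plane
        radius_mm = self.params.mother_vessel_diameter_fraction * min(
            g.extent_mm[0], g.extent_mm[1]
        ) / 2.0
        r_nodes = radius_mm / h[0]
        n_steps = max(16, int(2 * math.pi * r_nodes * 2))
        ring = []
        for s in range(n_steps):
            theta = 2 * math.pi * s / n_steps
            i = int(round(cx + r_nodes * math.cos(theta)))
            j = int(round(cy + r_nodes * math.sin(theta)))
            node = (i, j, kz)
            if not ring or ring[-1] != node:
                ring.append(node)
        if ring[0] == ring[-1]:
            ring.pop()
        r0 = self.params.mother_vessel_radius_mm
        for a, b in zip(ring, ring[1:] + ring[:1]):
            if a == b:
                continue
            self._add_segment(a, b, radius=r0, mother=True)
        self.inlet = ring[0]
        self.outlet = ring[len(ring) // 2]

    def _add_segment(self, a, b, radius: float, mother: bool = False) -> None:
        if a == b or self.graph.has_edge(a, b):
            return                      # never overwrite an existing segment
        h = self.grid.spacing_mm
        length = math.sqrt(sum(((a[i] - b[i]) * h[i]) ** 2 for i in range(3)))
        self.graph.add_edge(
            a, b, radius=radius, length=max(length, h[0] * 1e-3), mother=mother,
            collapsed=False, dead=False, perfused=mother, flow=0.0, shear=0.0,
        )
        self.segments_created += 1

    # -- derived node fields ----------------------------------------------
    def node_set(self):
        return set(self.graph.nodes)

    def vessel_mask(self, perfused_only: bool = True) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for a, b, attrs in self.graph.edges(data=True):
            if perfused_only and not attrs["perfused"]:
                continue
            mask[a] = True
            mask[b] = True
        return mask

    def tip_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for tip in self.tips:
            if tip.active:
                mask[tip.position] = True
        return mask

    def area_density(self) -> np.ndarray:
        """Vessel wall surface area per tissue volume (1/mm), at nodes of
        perfused segments; half of each segment's wall area to each endpoint."""
        h = self.grid.spacing_mm
        vol = h[0] * h[1] * h[2]
        out = np.zeros(self.grid.shape, dtype=float)
        for a, b, attrs in self.graph.edges(data=True):
            if not attrs["perfused"]:
                continue
            area = 2.0 * math.pi * attrs["radius"] * attrs["length"]
            out[a] += 0.5 * area / vol
            out[b] += 0.5 * area / vol
        return out

    # -- perfusion bookkeeping --------------------------------------------
    def update_perfusion(self) -> None:
        """A segment is perfused iff it lies on a conducting path between the
        mother-vessel inlet and outlet (collapsed/dead segments conduct
        nothing)."""
        active = nx.Graph(
            (a, b) for a, b, attrs in self.graph.edges(data=True)
            if not attrs["collapsed"] and not attrs["dead"] and attrs["radius"] > 0
        )
        if self.inlet in active and self.outlet in active:
            component = set(nx.node_connected_component(active, self.inlet))
            reach = component if self.outlet in component else set()
        else:
            reach = set()
        for a, b, attrs in self.graph.edges(data=True):
            conducting = not attrs["collapsed"] and not attrs["dead"]
            attrs["perfused"] = conducting and a in reach and b in reach

    # -- tip dynamics ------------------------------------------------------
    def tip_move_probabilities(self, tip: TipCell, fields, lattice: CellLattice,
                               density: np.ndarray, dt: float) -> MoveProbabilities:
        if not tip.active:
            raise ValueError("inactive tip")
        p = self.params
        node = tip.position
        c_v = fields["v"]
        chemo = p.beta_c / (1.0 + p.alpha * float(c_v[node]))
        grads = [(chemo, c_v), (p.beta_h, fields["e"])]
        w = move_weights(node, grads, lattice, density, p, p.D_tEC, dt,
                         self.grid.spacing_mm[0], exclude_occupied=False)
        return _normalize(w)

    def spawn_tip(self, node) -> TipCell:
        tip = TipCell(position=tuple(node))
        self.tips.append(tip)
        return tip

    def extend_sprout(self, tip: TipCell, direction, ec_state: EndothelialState) -> bool:
        """Advance a tip one node if its trailing stalk cells may proliferate;
        anastomose and retire the tip if it meets an existing vessel."""
        if not tip.active:
            raise ValueError("inactive tip")
        if direction is None or not ec_state.proliferation_eligible:
            tip.idle_age += 1
            return False
        new = tuple(tip.position[a] + direction[a] for a in range(3))
        if any(not (0 <= new[a] < self.grid.shape[a]) for a in range(3)):
            tip.idle_age += 1
            return False
        existing = new in self.graph and self.graph.degree(new) > 0
        self._add_segment(tip.position, new, radius=self.params.sprout_radius_mm)
        tip.position = new
        tip.idle_age = 0
        if existing:
            tip.active = False          # anastomosis: fuse and retire
        return True

    def branch_probability(self, c_v: float, c_a1: float, c_a2: float,
                           c_ag: float = 0.0) -> float:
        """Stalk-to-tip conversion probability per cell step: saturating in
        the (anti-VEGF-attenuated) VEGF level and in the ang-2:ang-1 ratio."""
        p = self.params
        v_eff = effective_vegf(c_v, c_ag, p)
        if v_eff <= 0.0:
            return 0.0
        ratio = c_a2 / c_a1 if c_a1 > 0 else (np.inf if c_a2 > 0 else 0.0)
        rterm = 1.0 if np.isinf(ratio) else ratio / (ratio + p.tip_ang_ratio_threshold)
        prob = p.branch_probability_max * v_eff / (v_eff + p.branch_vegf_half) * rterm
        return float(min(max(prob, 0.0), 1.0))

    def maybe_branch(self, segment, fields, rng) -> TipCell | None:
        """Possibly spawn a bifurcation tip from a live non-mother segment."""
        a, b = segment
        attrs = self.graph.edges[a, b]
        if attrs["mother"] or attrs["dead"]:
            return None
        node = a if rng.random() < 0.5 else b
        prob = self.branch_probability(
            float(fields["v"][node]), float(fields["a1"][node]),
            float(fields["a2"][node]), float(fields["ag"][node]),
        )
        if rng.random() < prob:
            return self.spawn_tip(node)
        return None

    def initiate_sprouts(self, fields, rng) -> list[TipCell]:
        """Poisson-thinned sprout initiation from mother-vessel nodes, using
        the same branching probability law."""
        new = []
        mother_nodes = {
            n for a, b, attrs in self.graph.edges(data=True) if attrs["mother"]
            for n in (a, b)
        }
        for node in sorted(mother_nodes):
            prob = self.branch_probability(
                float(fields["v"][node]), float(fields["a1"][node]),
                float(fields["a2"][node]), float(fields["ag"][node]),
            )
            if rng.random() < prob:
                new.append(self.spawn_tip(node))
        return new

    # -- remodeling --------------------------------------------------------
    def remodel(self, lattice: CellLattice, fields, rng, dt: float,
                flow_solved: bool = True) -> None:
        """Shear-set radius adaptation, compression collapse and VEGF-support
        stalk-cell death.  Requires segment flows/shears to be current."""
        if not flow_solved:
            raise RuntimeError("remodel requires a solved flow state")
        p = self.params
        density = lattice.live_density()
        for a, b, attrs in self.graph.edges(data=True):
            if attrs["mother"]:
                continue
            if attrs["dead"]:
                continue
            # wall shear adaptation toward target, clamped radius
            if attrs["perfused"]:
                tau = attrs["shear"]
                r = attrs["radius"]
                r += p.shear_adaptation_gain * r * (tau / p.shear_target - 1.0) * dt
                attrs["radius"] = float(
                    np.clip(r, p.vessel_radius_min_mm, p.vessel_radius_max_mm)
                )
            # mechanical compression by the crowded tumor
            dens = 0.5 * (float(density[a]) + float(density[b]))
            if dens > p.collapse_density_threshold:
                attrs["collapsed"] = True
            # stalk-cell death when VEGF support is insufficient
            c_v = 0.5 * (float(fields["v"][a]) + float(fields["v"][b]))
            c_ag = 0.5 * (float(fields["ag"][a]) + float(fields["ag"][b]))
            if rng.random() < sec_death_probability(c_v, c_ag, dt, p):
                attrs["dead"] = True
                attrs["collapsed"] = True
        self.update_perfusion()

    def step_tips(self, fields, lattice: CellLattice, rng, dt: float) -> None:
        """Advance all active tips one cellular step."""
        p = self.params
        density = lattice.live_density()
        for tip in list(self.tips):
            if not tip.active:
                continue
            tip.age += 1
            node = tip.position
            state = update_endothelial(
                EndothelialState(ECRole.STALK, True),
                float(fields["v"][node]), float(fields["a1"][node]),
                float(fields["a2"][node]), float(fields["ac"][node]),
                float(fields["ag"][node]), p,
            )
            if state.role == ECRole.DEAD:
                tip.active = False
                continue
            probs = self.tip_move_probabilities(tip, fields, lattice, density, dt)
            direction = probs.sample_direction(rng)
            self.extend_sprout(tip, direction, state)
            if tip.idle_age > p.tip_max_idle_age:
                tip.active = False
        self.tips = [t for t in self.tips if t.active]

    def step_branching(self, fields, rng) -> None:
        for seg in list(self.graph.edges):
            self.maybe_branch(seg, fields, rng)
        self.initiate_sprouts(fields, rng)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "inlet": list(self.inlet),
            "outlet": list(self.outlet),
            "edges": [
                [list(a), list(b), dict(attrs)]
                for a, b, attrs in self.graph.edges(data=True)
            ],
            "tips": [
                [list(t.position), t.age, t.idle_age, t.active] for t in self.tips
            ],
        }

    @classmethod
    def from_dict(cls, d: dict, grid, params) -> "VesselNetwork":
        net = cls.__new__(cls)
        net.grid = grid
        net.params = params
        net.graph = nx.Graph()
        net.tips = [
            TipCell(tuple(pos), age, idle, active)
            for pos, age, idle, active in d["tips"]
        ]
        net.segments_created = 0
        net.inlet = tuple(d["inlet"])
        net.outlet = tuple(d["outlet"])
        for a, b, attrs in d["edges"]:
            net.graph.add_edge(tuple(a), tuple(b), **attrs)
            net.segments_created += 1
        return net
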