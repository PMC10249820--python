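"""Discrete tumor-cell lattice: biased random-walk migration, division, crowding.

Tumor cells live on the same lattice as the finite-difference mesh (one cell
per node, 6-connected neighborhood).  Migration follows the hybrid
discretization of the tumor-cell density equation: a random-walk term
``D_TC`` plus haptotaxis up the ECM gradient (weight ``beta_h``) and cooption
up the vitality gradient (weight ``beta_cop``), with movement down-weighted
by tumor-induced solid pressure (local live-cell density excess).  Necrotic
nodes and the domain boundary are impenetrable.

Division requires the characteristic energy ``psi^ch``; the daughter is
placed by the movement-probability distribution and may displace viable (but
never necrotic) cells outward along the same direction, with the chain depth
capped.  The division probability decreases linearly with local live-cell
density and reaches zero at the density cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cells import Phenotype, StateMachineError, division_eligible, step_energy, \
    update_phenotype, vitality

#: 6-connected step directions, paired so direction d and d^1 are opposites.
DIRECTIONS = (
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
)

#: transitions a trajectory may exhibit (from -> to), including self-loops.
ALLOWED_TRANSITIONS = frozenset(
    [
        (Phenotype.STROMA, Phenotype.PROLIFERATIVE),   # division into a node
        (Phenotype.PROLIFERATIVE, Phenotype.PROLIFERATIVE),
        (Phenotype.PROLIFERATIVE, Phenotype.QUIESCENT),
        (Phenotype.QUIESCENT, Phenotype.PROLIFERATIVE),
        (Phenotype.QUIESCENT, Phenotype.QUIESCENT),
        (Phenotype.QUIESCENT, Phenotype.NECROTIC),
        (Phenotype.NECROTIC, Phenotype.NECROTIC),
    ]
)


@dataclass
class MoveProbabilities:
    """Stay + 6 neighbor probabilities for one lattice agent."""

    stay: float
    neighbors: tuple[float, ...]       # ordered as DIRECTIONS

    def __post_init__(self):
        total = self.stay + sum(self.neighbors)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {total}")
        if self.stay < 0 or any(p < 0 for p in self.neighbors):
            raise ValueError("probabilities must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array((self.stay, *self.neighbors))

    def sample_direction(self, rng) -> tuple[int, int, int] | None:
        """Draw a move; ``None`` means stay."""
        idx = rng.choice(7, p=self.as_array())
        return None if idx == 0 else DIRECTIONS[idx - 1]


@dataclass
class CellLattice:
    """Per-node tumor phenotype plus vitality and energy state."""

    phenotype: np.ndarray            # int8, Phenotype codes
    psi: np.ndarray                  # cellular energy
    upsilon: np.ndarray              # vitality (refreshed each step)
    divisions: int = 0
    aborted_divisions: int = 0
    transition_counts: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, shape) -> "CellLattice":
        return cls(
            phenotype=np.zeros(shape, dtype=np.int8),
            psi=np.zeros(shape, dtype=float),
            upsilon=np.zeros(shape, dtype=float),
        )

    @classmethod
    def seeded(cls, grid, radius_mm: float, psi0: float = 0.5) -> "CellLattice":
        """Spherical seed of proliferative cells at the domain center."""
        lat = cls.empty(grid.shape)
        h = grid.spacing_mm
        center = [(n - 1) / 2.0 * s for n, s in zip(grid.shape, h)]
        idx = np.indices(grid.shape)
        r2 = sum(((idx[a] * h[a] - center[a]) ** 2 for a in range(3)))
        mask = r2 <= radius_mm**2
        lat.phenotype[mask] = Phenotype.PROLIFERATIVE
        lat.psi[mask] = psi0
        return lat

    # -- masks and counts -------------------------------------------------
    @property
    def live_mask(self) -> np.ndarray:
        return (self.phenotype == Phenotype.PROLIFERATIVE) | (
            self.phenotype == Phenotype.QUIESCENT
        )

    @property
    def necrotic_mask(self) -> np.ndarray:
        return self.phenotype == Phenotype.NECROTIC

    def counts(self) -> dict[str, int]:
        ph = self.phenotype
        p = int((ph == Phenotype.PROLIFERATIVE).sum())
        q = int((ph == Phenotype.QUIESCENT).sum())
        n = int((ph == Phenotype.NECROTIC).sum())
        return {"proliferative": p, "quiescent": q, "necrotic": n,
                "viable": p + q, "total": p + q + n}

    def record_transition(self, old: int, new: int) -> None:
        key = (Phenotype(old), Phenotype(new))
        if key not in ALLOWED_TRANSITIONS:
            raise StateMachineError(f"forbidden phenotype transition {key}")
        self.transition_counts[key] = self.transition_counts.get(key, 0) + 1

    def live_density(self) -> np.ndarray:
        """Fraction of live cells among the 6 neighbors of each node
        (nodes beyond the boundary count as empty)."""
        live = self.live_mask.astype(float)
        acc = np.zeros_like(live)
        for d in DIRECTIONS:
            # shifted[x] = live[x + d]; zero the layer that wrapped around
            shifted = np.roll(live, shift=tuple(-s for s in d), axis=(0, 1, 2))
            for axis, step in enumerate(d):
                if step == 0:
                    continue
                sl = [slice(None)] * 3
                sl[axis] = -1 if step == 1 else 0
                shifted[tuple(sl)] = 0.0
            acc += shifted
        return acc / 6.0


def _in_bounds(node, shape) -> bool:
    return all(0 <= node[a] < shape[a] for a in range(3))


def move_weights(node, potential_grads, lattice: CellLattice, density: np.ndarray,
                 params, motility: float, dt: float, h: float,
                 exclude_occupied: bool = True) -> list[float]:
    """Raw directional weights for one lattice agent.

    ``potential_grads`` is a list of (weight, field) pairs; each contributes
    ``0.5 * weight * (field[nb] - field[node])`` to the directional bias,
    the standard finite-difference flux linearization.
    """
    shape = lattice.phenotype.shape
    scale = dt / h**2
    weights = []
    for d in DIRECTIONS:
        nb = (node[0] + d[0], node[1] + d[1], node[2] + d[2])
        if not _in_bounds(nb, shape):
            weights.append(0.0)
            continue
        if lattice.phenotype[nb] == Phenotype.NECROTIC:
            weights.append(0.0)
            continue
        if exclude_occupied and lattice.phenotype[nb] in (
            Phenotype.PROLIFERATIVE, Phenotype.QUIESCENT
        ):
            weights.append(0.0)
            continue
        w = motility
        for coeff, fld in potential_grads:
            w += 0.5 * coeff * (float(fld[nb]) - float(fld[node]))
        w = max(w, 0.0) * scale
        # solid-pressure resistance at the target node
        excess = max(0.0, float(density[nb]) - params.solid_pressure_threshold)
        w /= 1.0 + params.k_solid_pressure * excess
        weights.append(w)
    return weights


def _normalize(weights, max_move: float = 0.9) -> MoveProbabilities:
    total = sum(weights)
    if total > max_move:
        weights = [w * max_move / total for w in weights]
        total = max_move
    return MoveProbabilities(stay=1.0 - total, neighbors=tuple(weights))


def tc_move_probabilities(node, vit_field, ecm_field, lattice, density, params,
                          dt: float, h: float,
                          exclude_occupied: bool = True) -> MoveProbabilities:
    """Movement distribution of one live tumor cell (random walk + haptotaxis
    on the ECM gradient + cooption on the vitality gradient)."""
    ph = lattice.phenotype[node]
    if ph not in (Phenotype.PROLIFERATIVE, Phenotype.QUIESCENT):
        raise ValueError(f"node {node} does not hold a live tumor cell")
    grads = [(params.beta_h, ecm_field), (params.beta_cop, vit_field)]
    w = move_weights(node, grads, lattice, density, params, params.D_TC, dt, h,
                     exclude_occupied=exclude_occupied)
    return _normalize(w)


def division_probability(node, lattice: CellLattice, params) -> float:
    """Per-step division probability, decreasing linearly with the live-cell
    density of the 6-neighborhood; zero at the density cap."""
    live = 0
    shape = lattice.phenotype.shape
    for d in DIRECTIONS:
        nb = (node[0] + d[0], node[1] + d[1], node[2] + d[2])
        if _in_bounds(nb, shape) and lattice.phenotype[nb] in (
            Phenotype.PROLIFERATIVE, Phenotype.QUIESCENT
        ):
            live += 1
    return params.division_probability * max(0.0, 1.0 - live / 6.0)


def attempt_division(node, lattice: CellLattice, rng, params, vit_field,
                     ecm_field, density, dt: float, h: float) -> bool:
    """Try to divide the cell at ``node``; returns True on success.

    The daughter direction is drawn from the movement distribution (computed
    without occupancy exclusion, since daughters may displace viable cells).
    Occupied viable cells are pushed outward along the same direction; a chain
    blocked by necrosis, the boundary or the depth cap aborts the division.
    """
    if lattice.phenotype[node] != Phenotype.PROLIFERATIVE:
        raise ValueError("division requires a proliferative cell")
    if lattice.psi[node] < params.energy_ch:
        raise ValueError("division requires psi >= energy_ch")

    if rng.random() >= division_probability(node, lattice, params):
        return False
    probs = tc_move_probabilities(node, vit_field, ecm_field, lattice, density,
                                  params, dt, h, exclude_occupied=False)
    weights = np.array(probs.neighbors)
    if weights.sum() <= 0.0:
        lattice.aborted_divisions += 1
        return False
    weights = weights / weights.sum()
    d = DIRECTIONS[rng.choice(6, p=weights)]

    # find the first free node along d within the displacement-depth cap
    shape = lattice.phenotype.shape
    chain = []
    cur = node
    free = None
    for _ in range(int(params.displacement_depth)):
        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
        if not _in_bounds(cur, shape) or lattice.phenotype[cur] == Phenotype.NECROTIC:
            break
        if lattice.phenotype[cur] == Phenotype.STROMA:
            free = cur
            break
        chain.append(cur)
    if free is None:
        lattice.aborted_divisions += 1
        return False

    # shift displaced cells outward, farthest first; states move unchanged
    for src in reversed(chain):
        dst = (src[0] + d[0], src[1] + d[1], src[2] + d[2])
        lattice.phenotype[dst] = lattice.phenotype[src]
        lattice.psi[dst] = lattice.psi[src]
        lattice.upsilon[dst] = lattice.upsilon[src]
    daughter = (node[0] + d[0], node[1] + d[1], node[2] + d[2])
    psi_half = (lattice.psi[node] - params.energy_ch) / 2.0
    lattice.phenotype[daughter] = Phenotype.PROLIFERATIVE
    lattice.psi[daughter] = psi_half
    lattice.upsilon[daughter] = lattice.upsilon[node]
    lattice.psi[node] = psi_half
    lattice.divisions += 1
    lattice.record_transition(Phenotype.STROMA, Phenotype.PROLIFERATIVE)
    return True


def step_tumor(lattice: CellLattice, fields, rng, dt: float, params,
               h: float) -> CellLattice:
    """One cellular step: refresh vitality, integrate energy, update
    phenotypes, then move or divide every live cell in random order."""
    vit_field = vitality(fields["o2"], fields["g"], fields["co2"], params)
    density = lattice.live_density()
    live_nodes = np.argwhere(lattice.live_mask)
    if len(live_nodes) == 0:
        return lattice
    order = rng.permutation(len(live_nodes))
    c_ac = fields["ac"]
    for i in order:
        node = tuple(int(x) for x in live_nodes[i])
        old = int(lattice.phenotype[node])
        if old in (Phenotype.STROMA, Phenotype.NECROTIC):
            continue            # displaced away or died earlier this step
        u = float(vit_field[node])
        lattice.upsilon[node] = u
        drug = float(c_ac[node]) / params.c_ac_ch
        lattice.psi[node] = step_energy(lattice.psi[node], u, drug, dt, params)
        new = update_phenotype(Phenotype(old), u, float(lattice.psi[node]), params)
        lattice.phenotype[node] = new
        lattice.record_transition(old, new)
        if new == Phenotype.NECROTIC:
            continue
        if division_eligible(new, float(lattice.psi[node]), params):
            attempt_division(node, lattice, rng, params, vit_field,
                             fields["e"], density, dt, h)
        else:
            probs = tc_move_probabilities(node, vit_field, fields["e"], lattice,
                                          density, params, dt, h)
            d = probs.sample_direction(rng)
            if d is not None:
                dst = (node[0] + d[0], node[1] + d[1], node[2] + d[2])
                if lattice.phenotype[dst] == Phenotype.STROMA:
                    lattice.phenotype[dst] = lattice.phenotype[node]
                    lattice.psi[dst] = lattice.psi[node]
                    lattice.upsilon[dst] = lattice.upsilon[node]
                    lattice.phenotype[node] = Phenotype.STROMA
                    lattice.psi[node] = 0.0
                    lattice.upsilon[node] = 0.0
    return lattice
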