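"""Vascular hemodynamics and interstitial fluid mechanics.

Intravascular flow: each conducting segment is a Poiseuille resistor with
conductance ``g = pi r^4 / (8 mu L)``.  Kirchhoff balances at every interior
network node include a distributed transvascular leak (Starling law), with
Dirichlet pressures at the mother-vessel inlet and outlet.  Per-segment flow
and wall shear stress ``tau = 4 mu |Q| / (pi r^3)`` follow from the nodal
pressures.

Interstitial fluid: quasi-steady Darcy flow,

    -K lap(p_i) = Lp_eff (S/V) (P_vasc - p_i - sigma*dpi)  -  L_lym p_i ,

with the Starling source only at perfused-vessel nodes, the lymphatic sink
only in normal tissue (tumor lymphatics are nonfunctional), and p_i = 0 on
the domain faces.  VEGF makes walls leaky (Lp_eff grows with the effective
VEGF signal); the anti-VEGF drug attenuates that signal, restoring the
transvascular pressure difference -- the vascular-normalization mechanism
that lowers tumor IFP.  The interstitial velocity is Darcy's law,
``u_ins = -K grad(p_i)``.

The symmetric positive-definite Darcy operator is solved by conjugate
gradients to a configurable relative residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class FlowSolverError(RuntimeError):
    pass


@dataclass
class FlowState:
    """Vascular pressures/flows plus interstitial pressure and velocity."""

    node_pressure: dict = field(default_factory=dict)    # network node -> mmHg
    ifp: np.ndarray | None = None                        # interstitial pressure
    velocity: tuple | None = None                        # (ux, uy, uz), mm/day
    transvascular_flux: np.ndarray | None = None         # Jv per node, 1/day
    network_solved: bool = False
    ifp_solved: bool = False

    @property
    def solved(self) -> bool:
        return self.network_solved and self.ifp_solved


def effective_lp(c_v: float, c_ag: float, params) -> float:
    """Wall hydraulic conductivity with VEGF-induced leakiness and anti-VEGF
    attenuation (mm / (mmHg day))."""
    v_eff = c_v / (1.0 + params.k_ag_lp * c_ag)
    sat = v_eff / (v_eff + params.vegf_perm_half)
    return params.Lp_base * (1.0 + params.k_Lp_vegf * sat)


def segment_conductance(radius: float, length: float, mu: float) -> float:
    """Poiseuille conductance, mm^3 / (mmHg day)."""
    return math.pi * radius**4 / (8.0 * mu * length)


def solve_network_flow(network, params, fields=None, ifp=None) -> FlowState:
    """Solve nodal pressures and segment flows on the conducting network.

    ``ifp``/``fields`` supply the external pressure and VEGF/anti-VEGF levels
    for the transvascular leak; omitted, the leak uses zero interstitial
    pressure and baseline permeability.
    """
    g = network.graph
    mu = params.plasma_viscosity
    conducting = [
        (a, b, attrs) for a, b, attrs in g.edges(data=True)
        if not attrs["collapsed"] and not attrs["dead"]
    ]
    nodes = sorted({n for a, b, _ in conducting for n in (a, b)})
    if not nodes:
        raise FlowSolverError("no conducting segments")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = sp.lil_matrix((n, n))
    rhs = np.zeros(n)

    wall_area = {node: 0.0 for node in nodes}
    for a, b, attrs in conducting:
        cond = segment_conductance(attrs["radius"], attrs["length"], mu)
        ia, ib = index[a], index[b]
        A[ia, ia] += cond
        A[ib, ib] += cond
        A[ia, ib] -= cond
        A[ib, ia] -= cond
        area = 2.0 * math.pi * attrs["radius"] * attrs["length"]
        wall_area[a] += 0.5 * area
        wall_area[b] += 0.5 * area

    # transvascular leak (only meaningful on perfused segments' nodes)
    for node in nodes:
        i = index[node]
        c_v = float(fields["v"][node]) if fields is not None else 0.0
        c_ag = float(fields["ag"][node]) if fields is not None else 0.0
        lp = effective_lp(c_v, c_ag, params)
        leak = lp * wall_area[node]
        p_ext = (float(ifp[node]) if ifp is not None else 0.0) + params.osmotic_offset
        A[i, i] += leak
        rhs[i] += leak * p_ext

    # Dirichlet inlet/outlet
    for node, pressure in ((network.inlet, params.inlet_pressure),
                           (network.outlet, params.outlet_pressure)):
        if node not in index:
            raise FlowSolverError(
                "inlet/outlet disconnected from the conducting network"
            )
        i = index[node]
        A.rows[i] = [i]
        A.data[i] = [1.0]
        rhs[i] = pressure

    try:
        pressures = spla.spsolve(sp.csr_matrix(A), rhs)
    except Exception as err:  # singular system
        comps = "network may contain isolated components"
        raise FlowSolverError(f"singular vascular system: {comps}") from err
    if not np.all(np.isfinite(pressures)):
        raise FlowSolverError("non-finite vascular pressures")

    state = FlowState(node_pressure={n_: float(pressures[index[n_]]) for n_ in nodes})
    for a, b, attrs in g.edges(data=True):
        if attrs["collapsed"] or attrs["dead"] or a not in index or b not in index:
            attrs["flow"] = 0.0
            attrs["shear"] = 0.0
            continue
        cond = segment_conductance(attrs["radius"], attrs["length"], mu)
        q = cond * (pressures[index[a]] - pressures[index[b]])
        attrs["flow"] = float(q)
        attrs["shear"] = float(4.0 * mu * abs(q) / (math.pi * attrs["radius"] ** 3))
    state.network_solved = True
    return state


def _dirichlet_laplacian(shape, spacing) -> sp.csr_matrix:
    """-lap with homogeneous Dirichlet faces (SPD, 7-point)."""
    ax_ops = []
    for n, h in zip(shape, spacing):
        main = 2.0 * np.ones(n) / h**2
        off = -np.ones(n - 1) / h**2
        ax_ops.append(sp.diags([off, main, off], [-1, 0, 1]))
    ix, iy, iz = (sp.identity(n) for n in shape)
    return (
        sp.kron(sp.kron(ax_ops[0], iy), iz)
        + sp.kron(sp.kron(ix, ax_ops[1]), iz)
        + sp.kron(sp.kron(ix, iy), ax_ops[2])
    ).tocsr()


_lap_cache: dict = {}


def solve_ifp(fields, network, flow_state: FlowState, params, grid,
              tumor_mask: np.ndarray | None = None) -> FlowState:
    """Solve the steady interstitial pressure and Darcy velocity fields."""
    if not flow_state.network_solved:
        raise FlowSolverError("solve_ifp requires a solved network flow")
    shape = tuple(grid.shape)
    h = grid.spacing_mm
    vol = h[0] * h[1] * h[2]
    key = (shape, h)
    if key not in _lap_cache:
        _lap_cache[key] = _dirichlet_laplacian(shape, h)
    K = params.hydraulic_conductivity
    A = (K * _lap_cache[key]).tolil()

    source_coeff = np.zeros(shape)   # Lp*A/V at vessel nodes, 1/(mmHg day)
    source_rhs = np.zeros(shape)     # Lp*A/V * (P_v - sigma dpi)
    for a, b, attrs in network.graph.edges(data=True):
        if not attrs["perfused"]:
            continue
        area = 2.0 * math.pi * attrs["radius"] * attrs["length"]
        for node in (a, b):
            if fields is not None:
                lp = effective_lp(float(fields["v"][node]),
                                  float(fields["ag"][node]), params)
            else:
                lp = params.Lp_base
            coeff = lp * (0.5 * area / vol)
            p_v = flow_state.node_pressure.get(node, params.outlet_pressure)
            source_coeff[node] += coeff
            source_rhs[node] += coeff * (p_v - params.osmotic_offset)

    lym = np.zeros(shape)
    if tumor_mask is None:
        tumor_mask = np.zeros(shape, dtype=bool)
    lym[~tumor_mask] = params.lymphatic_conductance

    diag_extra = (source_coeff + lym).ravel()
    A = (A + sp.diags(diag_extra)).tocsr()
    rhs = source_rhs.ravel()

    if not rhs.any():
        p = np.zeros(shape)
    else:
        p0 = flow_state.ifp.ravel() if flow_state.ifp is not None else None
        p_flat, info = spla.cg(A, rhs, x0=p0, rtol=params.ifp_tolerance,
                               maxiter=10_000)
        if info != 0:
            res = np.linalg.norm(A @ p_flat - rhs) / max(np.linalg.norm(rhs), 1e-30)
            raise FlowSolverError(f"IFP CG failed (info={info}, residual={res:.2e})")
        p = p_flat.reshape(shape)

    ux, uy, uz = (np.zeros(shape) for _ in range(3))
    grads = np.gradient(p, *h, edge_order=1)
    velocity = tuple(-K * gr for gr in grads)

    jv = (source_rhs - source_coeff * p)   # Lp A/V (P_v - p - sigma dpi), 1/day
    flow_state.ifp = p
    flow_state.velocity = velocity
    flow_state.transvascular_flux = jv
    flow_state.ifp_solved = True
    return flow_state


def kirchhoff_residual(network, flow_state: FlowState, params, fields=None,
                       ifp=None) -> float:
    """Max |net nodal flow - transvascular leak| over interior network nodes,
    normalized by the largest segment flow.  Diagnostic for conservation."""
    g = network.graph
    net = {}
    area = {}
    for a, b, attrs in g.edges(data=True):
        if attrs["collapsed"] or attrs["dead"]:
            continue
        q = attrs["flow"]
        net[a] = net.get(a, 0.0) - q          # flow defined a -> b positive
        net[b] = net.get(b, 0.0) + q
        wall = 2.0 * math.pi * attrs["radius"] * attrs["length"]
        area[a] = area.get(a, 0.0) + 0.5 * wall
        area[b] = area.get(b, 0.0) + 0.5 * wall
    qmax = max((abs(attrs["flow"]) for _, _, attrs in g.edges(data=True)), default=1.0)
    worst = 0.0
    for node, imbalance in net.items():
        if node in (network.inlet, network.outlet):
            continue
        c_v = float(fields["v"][node]) if fields is not None else 0.0
        c_ag = float(fields["ag"][node]) if fields is not None else 0.0
        lp = effective_lp(c_v, c_ag, params)
        p_ext = (float(ifp[node]) if ifp is not None else 0.0) + params.osmotic_offset
        leak = lp * area[node] * (flow_state.node_pressure[node] - p_ext)
        worst = max(worst, abs(imbalance - leak))
    return worst / max(qmax, 1e-30)
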