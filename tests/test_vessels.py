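import numpy as np
import networkx as nx
import pytest

from tmesim.cells import ECRole, EndothelialState, Phenotype
from tmesim.fields import ScalarFieldSet
from tmesim.flow import solve_network_flow
from tmesim.grid import build_grid
from tmesim.tumor import CellLattice
from tmesim.vessels import TipCell, VesselNetwork

DT = 0.05


@pytest.fixture()
def net(unit_grid, params):
    network = VesselNetwork(unit_grid, params)
    network.update_perfusion()
    return network


def fresh_fields(grid, **levels):
    fs = ScalarFieldSet.initial(grid)
    for name, val in levels.items():
        fs.data[name][:] = val
    return fs


class TestMotherVessel:
    def test_closed_loop_in_mid_z_plane(self, net, unit_grid):
        mother = [(a, b) for a, b, at in net.graph.edges(data=True) if at["mother"]]
        kz = (unit_grid.shape[2] - 1) // 2
        nodes = {n for e in mother for n in e}
        assert all(n[2] == kz for n in nodes)
        ring = nx.Graph(mother)
        assert all(deg == 2 for _, deg in ring.degree)      # a single cycle
        assert nx.is_connected(ring)

    def test_mother_segments_perfused_from_start(self, net):
        assert all(at["perfused"] for _, _, at in net.graph.edges(data=True))

    def test_inlet_outlet_opposite(self, net):
        assert net.inlet != net.outlet
        assert net.inlet in net.graph and net.outlet in net.graph


class TestTipMovement:
    def test_isotropic_without_gradients(self, net, unit_grid, params):
        tip = net.spawn_tip((4, 4, 2))
        lat = CellLattice.empty(unit_grid.shape)
        fields = fresh_fields(unit_grid, v=0.2, e=1.0)
        probs = net.tip_move_probabilities(tip, fields, lat, lat.live_density(),
                                           DT)
        assert len(set(np.round(probs.neighbors, 15))) == 1

    def test_saturable_chemotaxis_coefficient(self, net, unit_grid, params):
        """Doubling VEGF so alpha*c_v goes 1 -> 2 scales the chemotactic bias
        by (1+1)/(1+2) = 2/3 at a fixed gradient."""
        lat = CellLattice.empty(unit_grid.shape)
        grad = 0.01
        idx = np.indices(unit_grid.shape)[0].astype(float)
        biases = []
        for level in (1.0, 2.0):
            fields = fresh_fields(unit_grid)
            fields.data["v"] = level + grad * (idx - 4)
            tip = TipCell((4, 4, 2))
            probs = net.tip_move_probabilities(tip, fields, lat,
                                               lat.live_density(), DT)
            biases.append(probs.neighbors[0] - probs.neighbors[1])
        assert biases[1] / biases[0] == pytest.approx(2.0 / 3.0, rel=1e-6)

    def test_necrotic_node_blocks_tip(self, net, unit_grid):
        lat = CellLattice.empty(unit_grid.shape)
        lat.phenotype[5, 4, 2] = Phenotype.NECROTIC
        tip = net.spawn_tip((4, 4, 2))
        fields = fresh_fields(unit_grid, v=0.2, e=1.0)
        probs = net.tip_move_probabilities(tip, fields, lat, lat.live_density(),
                                           DT)
        assert probs.neighbors[0] == 0.0

    def test_inactive_tip_rejected(self, net, unit_grid):
        tip = TipCell((4, 4, 2), active=False)
        lat = CellLattice.empty(unit_grid.shape)
        with pytest.raises(ValueError):
            net.tip_move_probabilities(tip, fresh_fields(unit_grid), lat,
                                       lat.live_density(), DT)


class TestSproutExtension:
    def test_eligible_extension_adds_segment(self, net):
        tip = net.spawn_tip((4, 4, 2))
        n0 = net.graph.number_of_edges()
        ok = net.extend_sprout(tip, (0, 0, 1), EndothelialState(ECRole.STALK, True))
        assert ok
        assert net.graph.number_of_edges() == n0 + 1
        assert tip.position == (4, 4, 3)

    def test_drug_blocked_proliferation_stalls_tip(self, net):
        """The anti-cancer drug killing dividing endothelial cells stops
        sprout extension -- the metronomic normalization mechanism."""
        tip = net.spawn_tip((4, 4, 2))
        n0 = net.graph.number_of_edges()
        ok = net.extend_sprout(tip, (0, 0, 1),
                               EndothelialState(ECRole.STALK, False))
        assert not ok
        assert net.graph.number_of_edges() == n0
        assert tip.idle_age == 1

    def test_anastomosis_fuses_and_retires_tip(self, net):
        tip = net.spawn_tip((4, 4, 2))
        net.extend_sprout(tip, (0, 0, 1), EndothelialState(ECRole.STALK, True))
        mother_node = min(
            n for a, b, at in net.graph.edges(data=True) if at["mother"]
            for n in (a, b)
        )
        # walk the tip onto an existing vessel node
        tip.position = (mother_node[0] - 1, mother_node[1], mother_node[2])
        net.extend_sprout(tip, (1, 0, 0), EndothelialState(ECRole.STALK, True))
        assert not tip.active
        assert net.graph.has_edge(tip.position, mother_node) or \
            tip.position == mother_node


class TestBranching:
    def test_zero_vegf_never_branches(self, net):
        assert net.branch_probability(0.0, 1.0, 5.0) == 0.0

    def test_probability_bounded_and_monotone(self, net, rng):
        prev = 0.0
        for v in np.linspace(0.0, 5.0, 21):
            p = net.branch_probability(v, 1.0, 2.0)
            assert 0.0 <= p <= 1.0
            assert p >= prev - 1e-12
            prev = p

    def test_monte_carlo_branch_frequency(self, net, unit_grid, params):
        """Observed stalk-to-tip conversion frequency matches the programmed
        probability within 3 sigma (binomial)."""
        rng = np.random.default_rng(2024)
        fields = fresh_fields(unit_grid, v=0.3, a1=1.0, a2=2.0)
        seg = next(
            (a, b) for a, b, at in net.graph.edges(data=True) if not at["mother"]
        ) if any(not at["mother"] for *_, at in net.graph.edges(data=True)) \
            else None
        if seg is None:
            tip = net.spawn_tip((4, 4, 2))
            net.extend_sprout(tip, (0, 0, 1), EndothelialState(ECRole.STALK, True))
            seg = (tip.position, (4, 4, 2))
        node = seg[0]
        p_prog = net.branch_probability(0.3, 1.0, 2.0)
        n = 10_000
        hits = sum(
            net.maybe_branch(seg, fields, rng) is not None for _ in range(n)
        )
        sigma = np.sqrt(n * p_prog * (1 - p_prog))
        assert abs(hits - n * p_prog) < 3 * sigma
        net.tips.clear()


class TestRemodeling:
    def _solve(self, net, params):
        state = solve_network_flow(net, params)
        return state

    def test_shear_at_target_is_fixed_point(self, net, unit_grid, params, rng):
        fields = fresh_fields(unit_grid, v=1.0)
        tip = net.spawn_tip((4, 4, 2))
        net.extend_sprout(tip, (0, 0, 1), EndothelialState(ECRole.STALK, True))
        seg = next(
            (at for *_, at in net.graph.edges(data=True) if not at["mother"])
        )
        seg["perfused"] = True
        seg["shear"] = params.shear_target
        r0 = seg["radius"]
        lat = CellLattice.empty(unit_grid.shape)
        net.remodel(lat, fields, rng, DT)
        assert seg["radius"] == pytest.approx(r0)

    def test_high_shear_dilates_toward_clamp(self, net, unit_grid, params, rng):
        fields = fresh_fields(unit_grid, v=1.0)
        tip = net.spawn_tip((4, 4, 2))
        net.extend_sprout(tip, (0, 0, 1), EndothelialState(ECRole.STALK, True))
        seg = next(at for *_, at in net.graph.edges(data=True) if not at["mother"])
        seg["perfused"] = True
        seg["shear"] = 10.0 * params.shear_target
        lat = CellLattice.empty(unit_grid.shape)
        radii = []
        for _ in range(400):
            net.remodel(lat, fields, rng, DT)
            seg["shear"] = 10.0 * params.shear_target
            seg["perfused"] = True
            radii.append(seg["radius"])
        assert all(b >= a for a, b in zip(radii, radii[1:]))
        assert radii[-1] == pytest.approx(params.vessel_radius_max_mm)

    def test_compression_collapse_zeroes_flow(self, net, unit_grid, params, rng):
        """A segment crowded by live tumor cells collapses and carries no
        flow after the next solve; the mother vessel is exempt."""
        fields = fresh_fields(unit_grid, v=1.0)
        tip = net.spawn_tip((4, 4, 4))
        net.extend_sprout(tip, (0, 0, 1), EndothelialState(ECRole.STALK, True))
        lat = CellLattice.empty(unit_grid.shape)
        lat.phenotype[2:7, 2:7, 2:7] = Phenotype.PROLIFERATIVE
        lat.psi[2:7, 2:7, 2:7] = 0.5
        net.remodel(lat, fields, rng, DT)
        seg = net.graph.edges[(4, 4, 4), (4, 4, 5)]
        assert seg["collapsed"]
        self._solve(net, params)
        assert seg["flow"] == 0.0
        assert all(
            not at["collapsed"] for *_, at in net.graph.edges(data=True)
            if at["mother"]
        )

    def test_perfusion_flags_match_graph_oracle(self, net, unit_grid, params,
                                                rng):
        """Perfused iff both endpoints reach inlet and outlet through
        conducting segments -- checked against an independent search."""
        fields = fresh_fields(unit_grid, v=0.5)
        for start in [(3, 2, 2), (5, 6, 2), (2, 5, 2)]:
            tip = net.spawn_tip(start)
            net.extend_sprout(tip, (0, 0, 1), EndothelialState(ECRole.STALK, True))
        rng2 = np.random.default_rng(5)
        for *_, at in net.graph.edges(data=True):
            if not at["mother"] and rng2.random() < 0.3:
                at["collapsed"] = True
        net.update_perfusion()
        oracle = nx.Graph(
            (a, b) for a, b, at in net.graph.edges(data=True)
            if not at["collapsed"] and not at["dead"]
        )
        for a, b, at in net.graph.edges(data=True):
            if at["collapsed"] or at["dead"]:
                expect = False
            else:
                expect = all(
                    n in oracle and nx.has_path(oracle, n, net.inlet)
                    and nx.has_path(oracle, n, net.outlet)
                    for n in (a, b)
                )
            assert at["perfused"] == expect

    def test_graph_has_no_dangling_segments_after_growth(self, unit_config):
        """Every segment endpoint is a graph node of degree >= 1 and tips sit
        on network nodes (validity audit after a short stochastic run)."""
        from tmesim.simulate import Simulation

        sim = Simulation(unit_config.replace(growth_days=0.5, treatment_days=0.0))
        sim.run()
        g = sim.network.graph
        assert all(g.degree(n) >= 1 for n in g.nodes)
        for tip in sim.network.tips:
            assert tip.position in g.nodes
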