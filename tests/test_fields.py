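import numpy as np
import pytest

from tmesim.fields import (SPECIES, NumericalError, ReactionContext,
                           ScalarFieldSet, laplacian, reaction_terms, stable_dt,
                           step_species, upwind_advection, vascular_exchange)
from tmesim.grid import build_grid


def empty_context(params, shape, plasma=None, flow_solved=False, **masks):
    defaults = dict(
        live_mask=np.zeros(shape, dtype=bool),
        necrotic_mask=np.zeros(shape, dtype=bool),
        tip_mask=np.zeros(shape, dtype=bool),
        vessel_mask=np.zeros(shape, dtype=bool),
        area_density=np.zeros(shape),
    )
    defaults.update(masks)
    return ReactionContext(params=params, plasma=plasma or {},
                           flow_solved=flow_solved, **defaults)


@pytest.fixture()
def unit_fields(unit_grid):
    return ScalarFieldSet.initial(unit_grid)


class TestTransportKernels:
    def test_uniform_field_unchanged_and_mass_conserved(self, unit_grid, params,
                                                        unit_fields):
        """No reactions, no flow: a uniform field is a steady state."""
        ctx = empty_context(params, unit_grid.shape)
        before = {s: unit_fields.total_mass(s) for s in ("o2", "g", "e")}
        snapshot = unit_fields["o2"].copy()
        dt = stable_dt(unit_grid.spacing_mm, params)
        for _ in range(20):
            step_species(unit_fields, None, ctx, dt)
        assert np.allclose(unit_fields["o2"], snapshot, atol=1e-13)
        for s, m in before.items():
            assert unit_fields.total_mass(s) == pytest.approx(m, rel=1e-12)

    def test_random_field_conserves_mass_under_diffusion(self, unit_grid, params,
                                                         rng):
        """Reflecting boundaries conserve every species' total mass."""
        fs = ScalarFieldSet.initial(unit_grid)
        fs.data["o2"] = rng.random(unit_grid.shape)
        ctx = empty_context(params, unit_grid.shape)
        m0 = fs.total_mass("o2")
        dt = stable_dt(unit_grid.spacing_mm, params)
        for _ in range(50):
            step_species(fs, None, ctx, dt)
        assert fs.total_mass("o2") == pytest.approx(m0, rel=1e-12)

    def test_advection_conserves_mass(self, unit_grid, params, rng):
        c = rng.random(unit_grid.shape)
        u = tuple(0.1 * rng.standard_normal(unit_grid.shape) for _ in range(3))
        h = unit_grid.spacing_mm
        dcdt = upwind_advection(c, u, h, r_f=0.9)
        assert abs(dcdt.sum()) * h[0] ** 3 < 1e-12

    def test_exponential_decay_closed_form(self, unit_grid, params):
        """First-order decay reproduces c0*exp(-kt) within 1% at kt=1."""
        lam = np.log(2.0) / params.ac_half_life_days
        fs = ScalarFieldSet.initial(unit_grid)
        fs.data["ac"][:] = 1.0
        ctx = empty_context(params, unit_grid.shape)
        t_end = 1.0 / lam
        n = 200
        dt = t_end / n
        for _ in range(n):
            step_species(fs, None, ctx, dt)
        assert fs["ac"][4, 4, 4] == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_point_impulse_matches_gaussian_kernel(self, params):
        """Pure diffusion of an impulse matches the free-space heat kernel in
        the interior, before the boundary is felt."""
        grid = build_grid((0.8, 0.8, 0.8), (17, 17, 17))
        h = grid.spacing_mm[0]
        D = params.D_o2
        fs = ScalarFieldSet.initial(grid)
        fs.data["o2"][:] = 0.0
        fs.data["o2"][8, 8, 8] = 1.0
        ctx = empty_context(params, grid.shape)
        sigma = 2.5 * h                      # resolved but far from the boundary
        t_end = sigma**2 / (2.0 * D)
        dt = stable_dt(grid.spacing_mm, params, safety=0.5)
        n = int(np.ceil(t_end / dt))
        for _ in range(n):
            step_species(fs, None, ctx, t_end / n)
        idx = np.indices(grid.shape)
        r2 = sum(((idx[a] - 8) * h) ** 2 for a in range(3))
        kernel = (4 * np.pi * D * t_end) ** -1.5 * np.exp(-r2 / (4 * D * t_end))
        kernel *= h**3                       # impulse mass is one node's worth
        interior = r2 <= (2 * h) ** 2
        rel = np.abs(fs["o2"][interior] - kernel[interior]) / kernel[interior]
        assert rel.max() < 0.02

    def test_grid_refinement_order_at_least_1p8(self, params):
        """Observed spatial convergence order of the diffusion step on a
        smooth cosine mode with exact Neumann solution."""
        D = params.D_o2
        L = 0.4
        t_end = 0.005
        errors = []
        for n in (9, 17):
            grid = build_grid((L, L, L), (n, n, n))
            h = grid.spacing_mm[0]
            x = np.arange(n) * h
            mode = np.cos(np.pi * x / L)
            exact0 = mode[:, None, None] * mode[None, :, None] * mode[None, None, :]
            fs = ScalarFieldSet.initial(grid)
            fs.data["o2"] = 1.0 + 0.5 * exact0
            ctx = empty_context(params, grid.shape)
            dt0 = 0.25 * h**2 / (6 * D)      # dt ~ h^2 keeps the error spatial
            steps = int(np.ceil(t_end / dt0))
            for _ in range(steps):
                step_species(fs, None, ctx, t_end / steps)
            decay = np.exp(-3 * D * (np.pi / L) ** 2 * t_end)
            exact = 1.0 + 0.5 * exact0 * decay
            errors.append(np.abs(fs["o2"] - exact).max())
        order = np.log2(errors[0] / errors[1])
        assert order >= 1.8

    def test_negativity_clamp_is_accounted(self, unit_grid, params):
        fs = ScalarFieldSet.initial(unit_grid)
        fs.data["m"][:] = 0.0
        fs.data["m"][4, 4, 4] = 1.0
        ctx = empty_context(params, unit_grid.shape)
        for _ in range(5):
            step_species(fs, None, ctx, stable_dt(unit_grid.spacing_mm, params))
        assert (fs["m"] >= 0).all()
        assert fs.clamped_mass["m"] >= 0.0

    def test_nan_detection_names_species(self, unit_grid, params):
        fs = ScalarFieldSet.initial(unit_grid)
        fs.data["v"][0, 0, 0] = np.nan
        with pytest.raises(NumericalError, match="'v'"):
            fs.check_finite(step=3)


class TestReactionTerms:
    def test_cell_free_node_has_no_cell_driven_reactions(self, unit_grid, params,
                                                         unit_fields):
        ctx = empty_context(params, unit_grid.shape)
        for species in ("o2", "g", "co2", "v", "m"):
            rate = reaction_terms(ctx, species, unit_fields)
            assert np.allclose(rate, 0.0), species

    def test_oxygenated_tumor_produces_no_vegf(self, unit_grid, params,
                                               unit_fields):
        live = np.zeros(unit_grid.shape, dtype=bool)
        live[4, 4, 4] = True
        ctx = empty_context(params, unit_grid.shape, live_mask=live)
        unit_fields.data["o2"][:] = params.c_o2_ch     # at characteristic level
        rate = reaction_terms(ctx, "v", unit_fields)
        assert rate[4, 4, 4] == 0.0
        unit_fields.data["o2"][:] = 0.2 * params.c_o2_ch
        assert reaction_terms(ctx, "v", unit_fields)[4, 4, 4] > 0.0

    def test_ecm_degradation_linear_in_mmp(self, unit_grid, params, unit_fields):
        ctx = empty_context(params, unit_grid.shape)
        unit_fields.data["m"][:] = 0.3
        r1 = reaction_terms(ctx, "e", unit_fields)
        unit_fields.data["m"][:] = 0.6
        r2 = reaction_terms(ctx, "e", unit_fields)
        assert np.allclose(r2, 2.0 * r1)
        assert (r1 <= 0).all()

    def test_unknown_species_rejected(self, unit_grid, params, unit_fields):
        ctx = empty_context(params, unit_grid.shape)
        with pytest.raises(KeyError):
            reaction_terms(ctx, "caffeine", unit_fields)


class TestVascularExchange:
    def test_requires_solved_flow(self, unit_grid, params, unit_fields):
        ctx = empty_context(params, unit_grid.shape, plasma={"o2": 1.0})
        with pytest.raises(RuntimeError):
            vascular_exchange(ctx, "o2", unit_fields)

    def test_no_vessel_no_source(self, unit_grid, params, unit_fields):
        ctx = empty_context(params, unit_grid.shape, plasma={"o2": 2.0},
                            flow_solved=True)
        assert np.allclose(vascular_exchange(ctx, "o2", unit_fields), 0.0)

    def test_equilibrium_gives_zero_source(self, unit_grid, params, unit_fields):
        vessel = np.zeros(unit_grid.shape, dtype=bool)
        vessel[4, 4, 4] = True
        ctx = empty_context(params, unit_grid.shape, plasma={"o2": 1.0},
                            flow_solved=True, vessel_mask=vessel,
                            area_density=vessel * 100.0)
        unit_fields.data["o2"][:] = 1.0      # equals plasma; no pressure term
        assert np.allclose(vascular_exchange(ctx, "o2", unit_fields), 0.0)

    def test_vegf_elevates_exchange_magnitude(self, unit_grid, params,
                                              unit_fields):
        """Leakier (high-VEGF) walls exchange faster at equal gradients."""
        vessel = np.zeros(unit_grid.shape, dtype=bool)
        vessel[2, 4, 4] = True
        vessel[6, 4, 4] = True
        ctx = empty_context(params, unit_grid.shape, plasma={"ac": 1.0},
                            flow_solved=True, vessel_mask=vessel,
                            area_density=vessel * 100.0)
        unit_fields.data["v"][6, 4, 4] = 1.0
        s = vascular_exchange(ctx, "ac", unit_fields)
        assert abs(s[6, 4, 4]) > abs(s[2, 4, 4]) > 0.0
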