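"""Finite-difference solver: diffusion operator, growth laws, necrosis
switch, stepping invariants (conservation, boundedness, symmetry,
self-convergence, anisotropic spread)."""

import numpy as np
import pytest

from gbmsim.fields import DensityField, GrowthParams, TensorField, VoxelGrid, \
    make_state
from gbmsim.phantoms import PhantomSpec, make_fiber_phantom, make_isotropic_phantom
from gbmsim.solver import (
    ModelVariant,
    diffusion_divergence,
    necrosis_update,
    proliferation,
    simulate,
    step,
)


def scalar_laplacian(values, mask, spacing):
    """Independent 7-point Laplacian with zero-flux mask boundary."""
    out = np.zeros_like(values)
    for a in range(3):
        h2 = spacing[a] ** 2
        for sign in (+1, -1):
            nb = np.roll(values, sign, axis=a)
            nb_mask = np.roll(mask, sign, axis=a)
            edge = [slice(None)] * 3
            edge[a] = 0 if sign == +1 else -1
            nb_mask = nb_mask.copy()
            nb_mask[tuple(edge)] = False
            out += np.where(mask & nb_mask, (nb - values) / h2, 0.0)
    return out


class TestDiffusionDivergence:
    def test_uniform_density_has_zero_divergence(self, full_grid):
        c = DensityField(full_grid, np.full(full_grid.shape, 3.0))
        D = TensorField.isotropic(full_grid, 0.1)
        assert np.allclose(diffusion_divergence(c, D), 0.0, atol=1e-12)

    def test_matches_scalar_laplacian_for_isotropic_tensor(self, full_grid):
        # discrete Gaussian bump
        x = np.arange(16) - 7.5
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        vals = np.exp(-(xx**2 + yy**2 + zz**2) / 12.0)
        c = DensityField(full_grid, vals)
        d = 0.0825
        D = TensorField.isotropic(full_grid, d)
        expected = d * scalar_laplacian(vals, full_grid.mask, full_grid.spacing)
        assert np.allclose(diffusion_divergence(c, D), expected, atol=1e-12)

    def test_grid_mismatch_rejected(self, full_grid):
        other = VoxelGrid((8, 8, 8), (1.0, 1.0, 1.0), np.ones((8, 8, 8), bool))
        c = DensityField(full_grid, np.zeros(full_grid.shape))
        D = TensorField.isotropic(other, 0.1)
        with pytest.raises(ValueError, match="grid"):
            diffusion_divergence(c, D)

    def test_spin_tensor_rejected(self, full_grid):
        c = DensityField(full_grid, np.zeros(full_grid.shape))
        D = TensorField.isotropic(full_grid, 0.1, kind="spin")
        with pytest.raises(ValueError, match="cell"):
            diffusion_divergence(c, D)


class TestProliferation:
    def test_logistic_vanishes_at_capacity(self, full_grid, params):
        c = DensityField(full_grid, np.full(full_grid.shape, params.c_m))
        assert np.allclose(proliferation(c, params), 0.0)

    def test_logistic_at_half_capacity(self, full_grid, params):
        c = DensityField(full_grid, np.full(full_grid.shape, params.c_m / 2))
        expected = 0.33 * (params.c_m / 2) * 0.5  # 0.0825 * c_m per day
        assert np.allclose(proliferation(c, params), expected)
        assert expected == pytest.approx(0.0825 * params.c_m)

    def test_exponential_definition(self, full_grid):
        p = GrowthParams(rho=0.1, growth_law="exponential")
        c = DensityField(full_grid, np.ones(full_grid.shape))
        assert np.allclose(proliferation(c, p), 0.1)

    def test_gompertz_zero_at_zero_density(self, full_grid):
        p = GrowthParams(rho=0.5, growth_law="gompertz")
        c = DensityField(full_grid, np.zeros(full_grid.shape))
        assert np.allclose(proliferation(c, p), 0.0)

    def test_gompertz_positive_below_capacity(self, full_grid):
        p = GrowthParams(rho=0.5, c_m=1e5, growth_law="gompertz")
        vals = np.full(full_grid.shape, 1e4)
        c = DensityField(full_grid, vals)
        expected = 0.5 * 1e4 * np.log(10.0)
        assert np.allclose(proliferation(c, p), expected)


class TestNecrosisUpdate:
    def test_one_day_decay_factor(self, full_grid, params):
        state = make_state(full_grid, (8, 8, 8), params.c_m, params)
        after = necrosis_update(state, params)
        assert after.c.values[8, 8, 8] == pytest.approx(0.9 * params.c_m)
        assert after.t == pytest.approx(1.0)

    def test_geometric_decay_over_ten_days(self, full_grid, params):
        state = make_state(full_grid, (8, 8, 8), params.c_m, params)
        for _ in range(10):
            state = necrosis_update(state, params)
        assert state.c.values[8, 8, 8] == pytest.approx(0.9**10 * params.c_m)
        assert state.c.values[8, 8, 8] == pytest.approx(0.3487 * params.c_m,
                                                        rel=1e-3)

    def test_eta_near_one_leaves_density_unchanged(self, full_grid):
        p = GrowthParams(rho=0.33, eta=1 - 1e-12)
        state = make_state(full_grid, (8, 8, 8), p.c_m, p)
        after = necrosis_update(state, p)
        assert after.c.values[8, 8, 8] == pytest.approx(p.c_m)

    def test_necrotic_set_never_shrinks(self, full_grid, params):
        state = make_state(full_grid, (8, 8, 8), params.c_m, params)
        for _ in range(20):
            new = necrosis_update(state, params)
            assert (new.necrotic >= state.necrotic).all()
            state = new


class TestStep:
    def test_zero_density_is_absorbing(self, full_grid, params):
        state = make_state(full_grid, (8, 8, 8), 1.0, params)
        state = state.replace(
            c=DensityField(full_grid, np.zeros(full_grid.shape)),
            m=np.zeros(full_grid.shape),
        )
        var = ModelVariant(diffusion="isotropic", necrosis=True)
        for _ in range(5):
            state = step(state, 0.0825, params, var)
        assert np.all(state.c.values == 0.0)

    def test_determinism(self, full_grid, params):
        var = ModelVariant(diffusion="isotropic", necrosis=True)
        runs = []
        for _ in range(2):
            s = make_state(full_grid, (8, 8, 8), 0.1 * params.c_m, params)
            runs.append(simulate(s, 0.0825, params, var, n_days=10))
        for a, b in zip(*runs):
            assert np.array_equal(a.c.values, b.c.values)
            assert np.array_equal(a.necrotic, b.necrotic)

    def test_boundedness_and_max_history(self, full_grid, params):
        var = ModelVariant(diffusion="isotropic", necrosis=True)
        state = make_state(full_grid, (8, 8, 8), params.c_m, params)
        for _ in range(20):
            state = step(state, 0.0825, params, var)
            assert state.c.values.min() >= 0.0
            assert state.c.values.max() <= params.c_m
            assert (state.m >= state.c.values - 1e-9).all()

    def test_max_density_monotone_without_necrosis(self, params):
        spec = PhantomSpec(shape=(24, 24, 24), medium="isotropic",
                           mean_diffusivity=0.0825)
        grid, _ = make_isotropic_phantom(spec)
        var = ModelVariant(diffusion="isotropic", necrosis=False)
        state = make_state(grid, (12, 12, 12), 0.1 * params.c_m, params)
        snaps = simulate(state, 0.0825, params, var, n_days=25)
        peaks = [s.c.values.max() for s in snaps]
        # after the initial diffusive dilution of the point seed the peak
        # grows monotonically toward c_m
        trough = int(np.argmin(peaks))
        assert all(b >= a - 1e-9 for a, b in zip(peaks[trough:], peaks[trough + 1:]))
        assert peaks[-1] <= params.c_m

    def test_isotropic_run_symmetric_under_axis_permutation(self, params):
        spec = PhantomSpec(shape=(24, 24, 24), medium="isotropic",
                           mean_diffusivity=0.0825)
        grid, tensor = make_isotropic_phantom(spec)
        state = make_state(grid, (12, 12, 12), 0.1 * params.c_m, params)
        var = ModelVariant(diffusion="tensor", necrosis=False)
        final = simulate(state, tensor, params, var, n_days=10)[-1].c.values
        for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            assert np.allclose(final, np.transpose(final, perm), atol=1e-9)

    def test_nonfinite_density_fails_loudly(self, full_grid, params):
        state = make_state(full_grid, (8, 8, 8), 0.5 * params.c_m, params)
        bad = np.where(state.c.values > 0, np.inf, 0.0)
        # bypass DensityField validation to emulate corruption mid-run
        object.__setattr__(state.c, "values", bad)
        var = ModelVariant(diffusion="isotropic", necrosis=False)
        with pytest.raises((FloatingPointError, ValueError),
                           match="finite|voxel"):
            step(state, 0.0825, params, var)


class TestSimulate:
    def test_zero_days_returns_initial_only(self, full_grid, params):
        state = make_state(full_grid, (8, 8, 8), 1.0, params)
        var = ModelVariant(diffusion="isotropic", necrosis=True)
        snaps = simulate(state, 0.0825, params, var, n_days=0)
        assert len(snaps) == 1 and snaps[0] is state

    def test_snapshots_include_first_and_last(self, full_grid, params):
        state = make_state(full_grid, (8, 8, 8), 1.0, params)
        var = ModelVariant(diffusion="isotropic", necrosis=True)
        snaps = simulate(state, 0.0825, params, var, n_days=7, snapshot_every=3)
        assert [s.t for s in snaps] == [0.0, 3.0, 6.0, 7.0]


class TestConservation:
    def test_mass_conserved_with_pure_diffusion(self):
        """Zero-flux tensor diffusion conserves total cell count."""
        spec = PhantomSpec(shape=(20, 20, 20), medium="fiber_bundle",
                           mean_diffusivity=0.1, fa_target=0.7,
                           fiber_radius_mm=4.0)
        grid, tensor = make_fiber_phantom(spec)
        p = GrowthParams(rho=0.0, c_m=1e5)
        state = make_state(grid, (10, 10, 10), 0.5e5, p)
        var = ModelVariant(diffusion="tensor", necrosis=False)
        m0 = state.c.total_cells()
        for _ in range(100):
            state = step(state, tensor, p, var)
        drift = abs(state.c.total_cells() - m0) / m0
        assert drift < 1e-10


class TestSelfConvergence:
    def test_halving_substep_changes_field_little(self, params):
        spec = PhantomSpec(shape=(32, 32, 32), medium="isotropic",
                           mean_diffusivity=0.0825)
        grid, _ = make_isotropic_phantom(spec)
        var = ModelVariant(diffusion="isotropic", necrosis=False)

        def run(min_substeps):
            s = make_state(grid, (16, 16, 16), 0.1 * params.c_m, params)
            return simulate(s, 0.0825, params, var, n_days=20,
                            min_substeps=min_substeps)[-1].c.values

        from gbmsim.metrics import equivalent_radius

        fields = {n: run(n) for n in (2, 4, 8)}
        # front position agrees to within half a voxel under refinement
        r = {n: equivalent_radius(f >= 0.16 * params.c_m, (1.0, 1.0, 1.0))
             for n, f in fields.items()}
        assert abs(r[4] - r[8]) < 0.5
        # total mass converges at first order: successive halvings shrink
        # the change by about a factor of two
        d1 = abs(fields[4].sum() - fields[2].sum())
        d2 = abs(fields[8].sum() - fields[4].sum())
        assert d2 < 0.75 * d1


class TestAnisotropy:
    def test_fiber_seeded_tumor_elongates_along_fiber(self, params):
        spec = PhantomSpec(shape=(40, 40, 40), medium="fiber_bundle",
                           mean_diffusivity=0.0825, fa_target=0.8,
                           fiber_axis=(1.0, 0.0, 0.0))
        grid, tensor = make_fiber_phantom(spec)
        state = make_state(grid, (20, 20, 20), 0.1 * params.c_m, params)
        var = ModelVariant(diffusion="tensor", necrosis=False)
        final = simulate(state, tensor, params, var, n_days=30)[-1]
        support = final.c.values >= 0.16 * params.c_m
        idx = np.argwhere(support)
        extent = idx.max(axis=0) - idx.min(axis=0)
        assert extent[0] > extent[1]
        assert extent[0] > extent[2]
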