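"""Grid-cell simulator: hexagonal maps, coherent realignment, pseudo-voxels."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from subgen import (
    EnvironmentRealignment,
    GridModule,
    GridModuleSpec,
    VoxelGrouping,
    add_voxel_noise,
    build_module,
    default_module_specs,
    flatten,
    generalization_gap,
    grid_cell_map,
    group_into_voxels,
    power_sweep,
    pseudo_voxel_pair,
    realign,
    simulate_place_cells,
)
from subgen.gridsim import _group_membership, realignment_permutation


class TestGridCellMap:
    def test_rectified_nonnegative(self, tiny_module_spec):
        m = grid_cell_map(tiny_module_spec, (0.2, 0.7))
        assert m.min() >= 0
        assert m.max() > 1  # three cosines peak near 3

    def test_lattice_vector_phase_wraps(self, tiny_module_spec):
        m1 = grid_cell_map(tiny_module_spec, (0.25, 0.5))
        m2 = grid_cell_map(tiny_module_spec, (1.25, 0.5))
        assert np.allclose(m1, m2, atol=1e-10)

    def test_autocorrelation_peak_at_spacing(self):
        """The six inner autocorrelation peaks sit at radius ≈ spacing."""
        spec = GridModuleSpec(spacing=2.95, orientation=0.2, resolution=50)
        m = grid_cell_map(spec, (0.1, 0.4))
        m = m - m.mean()
        ac = fftconvolve(m, m[::-1, ::-1])
        bin_size = spec.box_size / spec.resolution
        c = np.array(ac.shape) // 2
        ii, jj = np.indices(ac.shape)
        r = np.hypot(ii - c[0], jj - c[1]) * bin_size
        ring = lambda lo, hi: ac[(r >= lo) & (r < hi)].max()
        radii = np.arange(0.5 * spec.spacing, 1.5 * spec.spacing, bin_size)
        profile = [ring(x, x + bin_size) for x in radii]
        peak_radius = radii[int(np.argmax(profile))] + bin_size / 2
        assert abs(peak_radius - spec.spacing) <= 1.5 * bin_size


class TestBuildModule:
    def test_default_cell_count(self):
        module = build_module(default_module_specs()[0])
        assert module.spec.phase_lattice == (116, 116)
        assert module.n_cells == 13456

    def test_mean_map_nearly_constant(self):
        """Phases tile the rhombus, so the module-average map is flat."""
        module = build_module(default_module_specs()[1])
        mean_map = module.maps().mean(axis=0, dtype=np.float64)
        assert mean_map.std() / mean_map.mean() < 0.05

    def test_full_lattice_wraparound(self, tiny_module_spec):
        module = build_module(tiny_module_spec)
        maps = module.maps(np.float64)
        # phase (0,0) and phase shifted by one full lattice vector coincide
        direct = grid_cell_map(tiny_module_spec, (1.0, 1.0))
        assert np.allclose(maps[0], direct, atol=1e-9)


class TestRealign:
    def test_zero_shift_identity(self, tiny_module_spec):
        m1 = build_module(tiny_module_spec)
        m2 = realign(m1, EnvironmentRealignment((0.0, 0.0)))
        assert np.array_equal(m1.maps(), m2.maps())

    def test_correlations_preserved_up_to_permutation(self, tiny_module_spec):
        """A lattice-snapped module shift relabels the population, so the
        cell-pair correlation matrix is exactly conjugated by the known
        permutation."""
        m1 = build_module(tiny_module_spec)
        env2 = EnvironmentRealignment((0.34, 0.71))
        m2 = realign(m1, env2)
        perm = realignment_permutation(m1, env2)
        c1 = np.corrcoef(m1.maps(np.float64).reshape(m1.n_cells, -1))
        c2 = np.corrcoef(m2.maps(np.float64).reshape(m2.n_cells, -1))
        assert np.abs(c2 - c1[np.ix_(perm, perm)]).max() < 1e-6

    def test_population_subspace_preserved(self, tiny_module_spec):
        """End-to-end: the full-population within-vs-across AUC gap is ~0 —
        coactivation preservation, the defining grid property."""
        m1 = build_module(tiny_module_spec)
        m2 = realign(m1, EnvironmentRealignment((0.4, 0.15)))
        _, _, gap = generalization_gap(
            flatten(m1.stack()), flatten(m2.stack()), "zscored"
        )
        # the phase-difference covariance is translation invariant up to
        # finite-box boundary effects, so the gap is ~0 but not exactly 0
        assert abs(gap) < 1e-2


class TestVoxelGrouping:
    def test_group_sizes_equal(self):
        for ratio in (0.0, 0.37, 1.0):
            rng = np.random.default_rng(0)
            phases = np.random.default_rng(1).uniform(0, 1, (13456, 2))
            members = _group_membership(
                13456, phases, VoxelGrouping(4, ratio, 0), rng
            )
            sizes = [len(m) for m in members]
            assert sizes == [3364] * 4
            assert np.array_equal(
                np.sort(np.concatenate(members)), np.arange(13456)
            )

    def test_uneven_counts_within_one(self):
        rng = np.random.default_rng(0)
        phases = np.random.default_rng(1).uniform(0, 1, (11, 2))
        members = _group_membership(11, phases, VoxelGrouping(3, 0.5, 0), rng)
        sizes = sorted(len(m) for m in members)
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 11

    def test_phase_grouped_voxels_carry_signal(self, tiny_module_spec):
        """Random grouping averages away the grid pattern; phase grouping
        keeps it (spatial variance ratio ≥ 10)."""
        module = build_module(GridModuleSpec(2.0, 0.3, (24, 24), 0.0, 10.0, 25))
        by_phase = group_into_voxels([module], VoxelGrouping(4, 0.0, 0))
        random = group_into_voxels([module], VoxelGrouping(4, 1.0, 0))
        var_phase = by_phase.values.var(axis=1).mean()
        var_random = random.values.var(axis=1).mean()
        assert var_phase > 10 * var_random

    def test_grouping_commutes_with_realignment(self, tiny_module_spec):
        """Voxel membership is environment-independent: realign-then-group
        equals averaging the realigned member cells of the original groups."""
        m1 = build_module(tiny_module_spec)
        m2 = realign(m1, EnvironmentRealignment((0.6, 0.2)))
        grouping = VoxelGrouping(4, 0.5, 3)
        v2 = group_into_voxels([m2], grouping)
        rng = np.random.default_rng(np.random.SeedSequence(3).spawn(1)[0])
        members = _group_membership(m1.n_cells, m1.phases, grouping, rng)
        maps2 = m2.maps().reshape(m2.n_cells, -1)
        maps2 = maps2 / maps2.max(axis=1, keepdims=True)
        manual = np.vstack(
            [maps2[idx].mean(axis=0, dtype=np.float64) for idx in members]
        )
        assert np.allclose(v2.values, manual)

    def test_too_many_groups_rejected(self, tiny_module_spec):
        module = build_module(GridModuleSpec(2.0, 0.0, (2, 2), 0.0, 10.0, 25))
        with pytest.raises(ValueError):
            group_into_voxels([module], VoxelGrouping(5, 0.0, 0))


class TestVoxelNoise:
    def test_sigma_zero_identity(self, rng):
        a = pseudo_matrix(rng)
        out = add_voxel_noise(a, 0.0, 1)
        assert np.array_equal(out.values, a.values)

    def test_sample_sd_matches_sigma(self, rng):
        a = pseudo_matrix(rng)
        out = add_voxel_noise(a, 0.07, 2)
        added = out.values - a.values
        assert added.std() == pytest.approx(0.07, rel=0.05)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            add_voxel_noise(pseudo_matrix(rng), -0.1, 0)


def pseudo_matrix(rng):
    from subgen import ActivityMatrix

    return ActivityMatrix(rng.random((16, 100)))


class TestPlaceCells:
    def test_no_remap_zero_gap(self):
        s1, s2 = simulate_place_cells(12, seed=4, resolution=25, remap=False)
        _, _, gap = generalization_gap(flatten(s1), flatten(s2), "zscored")
        assert gap == pytest.approx(0.0, abs=1e-12)

    def test_remap_breaks_subspace_vs_grids(self, tiny_module_spec):
        """The grid/place dissociation: a coherently realigned grid population
        keeps a smaller AUC gap than a fully remapped place population."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            phases = r.uniform(0, 1, (25, 2))
            g1 = GridModule(tiny_module_spec, EnvironmentRealignment(), phases)
            g2 = GridModule(
                tiny_module_spec, EnvironmentRealignment(tuple(r.uniform(0, 1, 2))),
                phases,
            )
            _, _, grid_gap = generalization_gap(
                flatten(g1.stack()), flatten(g2.stack()), "zscored"
            )
            p1, p2 = simulate_place_cells(25, seed=r, resolution=25)
            _, _, place_gap = generalization_gap(
                flatten(p1), flatten(p2), "zscored"
            )
            wins += grid_gap < place_gap
        assert wins >= 9

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            simulate_place_cells(1, seed=0)


class TestPowerSweep:
    def test_single_point_single_row(self, tiny_module_spec):
        specs = [tiny_module_spec]
        df = power_sweep([0.0], [0.0], n_reps=1, seed=9, specs=specs)
        assert len(df) == 1
        assert {"auc_within", "auc_between", "gap"} <= set(df.columns)
        assert abs(df.loc[0, "gap"]) < 0.05

    def test_seed_reproducibility(self, tiny_module_spec):
        specs = [tiny_module_spec]
        df1 = power_sweep([0.0, 1.0], [0.0, 0.05], seed=3, specs=specs)
        df2 = power_sweep([0.0, 1.0], [0.0, 0.05], seed=3, specs=specs)
        assert df1.equals(df2)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            power_sweep([], [0.0])
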