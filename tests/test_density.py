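import math

import numpy as np
import pytest

from helpers import build_system

from lipidsat.constants import GAS_CONSTANT_KJ
from lipidsat.density import (
    DensityGrid,
    RegionMask,
    accumulate_density,
    aligned_positions,
    binding_free_energy,
    bulk_mask,
    site_mask,
)


def uniform_grid(shape=(20, 20, 20), bin_size=0.1, fill=1):
    counts = np.full(shape, fill, dtype=np.int64)
    edges = tuple(bin_size * np.arange(n + 1) for n in shape)
    return DensityGrid(
        counts=counts,
        edges=edges,
        bin_size=bin_size,
        center=np.array([s * bin_size / 2 for s in shape]),
        samples=int(counts.sum()),
    )


def two_level_grid(site_value, bulk_value, shape=(10, 10, 10)):
    """Grid with a distinct density level in the first x-slab."""
    counts = np.full(shape, bulk_value, dtype=np.int64)
    counts[0] = site_value
    edges = tuple(0.1 * np.arange(n + 1) for n in shape)
    grid = DensityGrid(
        counts=counts,
        edges=edges,
        bin_size=0.1,
        center=np.array([0.5, 0.5, 0.5]),
        samples=int(counts.sum()),
    )
    site_arr = np.zeros(shape, bool)
    site_arr[0] = True
    bulk_arr = np.zeros(shape, bool)
    bulk_arr[1:] = True
    return grid, RegionMask(site_arr, "site"), RegionMask(bulk_arr, "bulk")


class TestAccumulateDensity:
    def test_single_bead_lands_in_one_voxel(self):
        system = build_system(
            [{"protein:0": [[5.0, 5.0, 5.0]], "CHOL:0": [[5.05, 5.05, 5.05]]}]
        )
        grid = accumulate_density(
            system, system.beads_of_molecule(1), extents=(2, 2, 2), align=False
        )
        assert grid.samples == 1
        assert (grid.counts == 1).sum() == 1

    def test_count_conservation(self, small_spatial_system):
        model, system = small_spatial_system
        chol = np.flatnonzero(
            np.isin(system.bead_to_molecule, system.molecules_of_species("CHOL"))
        )
        grid = accumulate_density(
            system, chol, extents=model.box, bin_size=0.3, align=False
        )
        assert grid.samples == chol.size * system.n_frames
        assert grid.counts.sum() == grid.samples

    def test_uniform_sampling_chi_square_sane(self, rng):
        # 1e4 uniform points over an 8-voxel grid: chi-square far below the
        # p~1e-6 cutoff for 7 degrees of freedom
        points = rng.uniform(0, 1.0, size=(10_000, 3))
        frames = [{"protein:0": [[0.5, 0.5, 0.5]], "CHOL:0": points[i]} for i in range(len(points))]
        system = build_system(frames, box=(1.0, 1.0, 1.0))
        chol_bead = system.beads_of_molecule(1)
        grid = accumulate_density(
            system,
            chol_bead,
            center=np.array([0.5, 0.5, 0.5]),
            extents=(1.0, 1.0, 1.0),
            bin_size=0.5,
            align=False,
        )
        expected = grid.samples / grid.counts.size
        chi2 = float(((grid.counts - expected) ** 2 / expected).sum())
        assert grid.samples == 10_000
        assert chi2 < 40.0

    def test_empty_selection_errors(self, small_spatial_system):
        _, system = small_spatial_system
        with pytest.raises(ValueError, match="empty"):
            accumulate_density(system, np.array([], dtype=int))

    def test_alignment_undoes_z_rotation(self):
        # protein triangle + one offset CHOL bead, rotated by 40 deg in frame 2
        protein = np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0], [5.0, 6.5, 5.0]])
        chol = np.array([[7.0, 5.0, 5.0]])
        theta = math.radians(40.0)
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        center = protein.mean(axis=0)
        frames = [
            {"protein:0": protein, "CHOL:0": chol},
            {
                "protein:0": (protein - center) @ rot.T + center,
                "CHOL:0": (chol - center) @ rot.T + center,
            },
        ]
        system = build_system(frames)
        aligned = aligned_positions(system, align=True)
        np.testing.assert_allclose(aligned[1], aligned[0], atol=1e-9)


class TestMasks:
    def test_minimal_radius_selects_a_voxel(self):
        grid = uniform_grid()
        mask = site_mask(grid, grid.center, radius=0.11)
        assert mask.n_voxels >= 1

    def test_radius_covering_grid_selects_all(self):
        grid = uniform_grid()
        mask = site_mask(grid, grid.center, radius=100.0)
        assert mask.n_voxels == grid.counts.size

    def test_sphere_volume_within_ten_percent(self):
        grid = uniform_grid(shape=(40, 40, 40))
        radius = 10 * grid.bin_size
        mask = site_mask(grid, grid.center, radius)
        assert mask.n_voxels * grid.voxel_volume == pytest.approx(
            4 / 3 * math.pi * radius**3, rel=0.1
        )

    def test_radius_not_above_bin_size_errors(self):
        grid = uniform_grid()
        with pytest.raises(ValueError):
            site_mask(grid, grid.center, radius=0.05)

    def test_bulk_full_grid_without_protein(self):
        grid = uniform_grid()
        mask = bulk_mask(grid, None, z_slab=(-1e9, 1e9))
        assert mask.n_voxels == grid.counts.size

    def test_bulk_empty_when_protein_everywhere(self):
        grid = uniform_grid()
        with pytest.raises(ValueError, match="empty"):
            bulk_mask(
                grid,
                np.array([[1.0, 1.0, 1.0]]),
                z_slab=(-1e9, 1e9),
                min_protein_distance=1e6,
            )

    def test_bulk_disjoint_from_excluded_site(self):
        grid = uniform_grid()
        site = site_mask(grid, grid.center, radius=0.3)
        bulk = bulk_mask(grid, None, z_slab=(-1e9, 1e9), exclude=[site])
        assert not np.any(site.mask & bulk.mask)


class TestBindingFreeEnergy:
    def test_equal_densities_give_zero(self):
        grid, site, bulk = two_level_grid(4, 4)
        assert binding_free_energy(grid, site, bulk, 310.0) == pytest.approx(0.0)

    def test_ratio_fifty(self):
        grid, site, bulk = two_level_grid(100, 2)
        value = binding_free_energy(grid, site, bulk, 310.0)
        assert value == pytest.approx(-GAS_CONSTANT_KJ * 310.0 * math.log(50.0))
        assert value == pytest.approx(-10.08, abs=0.01)

    def test_ratio_ten(self):
        grid, site, bulk = two_level_grid(30, 3)
        assert binding_free_energy(grid, site, bulk, 310.0) == pytest.approx(
            -5.93, abs=0.01
        )

    def test_doubling_counts_leaves_dg_unchanged(self):
        grid, site, bulk = two_level_grid(100, 2)
        doubled, _, _ = two_level_grid(200, 4)
        assert binding_free_energy(grid, site, bulk, 310.0) == pytest.approx(
            binding_free_energy(doubled, site, bulk, 310.0)
        )

    def test_monotone_in_site_density(self):
        values = []
        for site_value in (10, 20, 40, 80):
            grid, site, bulk = two_level_grid(site_value, 5)
            values.append(binding_free_energy(grid, site, bulk, 310.0))
        assert values == sorted(values, reverse=True)

    def test_zero_site_density_warns_and_returns_inf(self):
        grid, site, bulk = two_level_grid(0, 5)
        with pytest.warns(UserWarning):
            assert binding_free_energy(grid, site, bulk, 310.0) == math.inf

    def test_overlapping_masks_rejected(self):
        grid, site, _ = two_level_grid(5, 5)
        overlapping = RegionMask(mask=np.ones(grid.counts.shape, bool), kind="bulk")
        with pytest.raises(ValueError, match="disjoint"):
            binding_free_energy(grid, site, overlapping, 310.0)


class TestExport:
    def test_dx_round_trip(self, tmp_path):
        from gridData import Grid

        grid = uniform_grid(shape=(5, 5, 5))
        path = tmp_path / "density.dx"
        grid.export_dx(path)
        loaded = Grid(str(path))
        np.testing.assert_allclose(loaded.grid, grid.density)
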