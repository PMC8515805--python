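import math

import numpy as np
import pytest

from lipidsat.constants import GAS_CONSTANT_KJ
from lipidsat.synthetic import (
    KineticSiteModel,
    SiteRegion,
    SpatialEnsembleModel,
    generate_saturation_dataset,
    simulate_contact_series,
    simulate_snapshot_ensemble,
)


class TestKineticModel:
    def test_ground_truth_kd(self):
        model = KineticSiteModel(k_on_per_conc=0.01, k_off=0.1)
        assert model.ground_truth_kd == pytest.approx(10.0)

    def test_symmetric_rates_give_half_occupancy(self):
        model = KineticSiteModel(k_on_per_conc=0.02, k_off=0.2, n_residues=1)
        series = simulate_contact_series(model, free_ligand=10.0, frames=100_000, seed=5)
        occupancy = series.residue_states.mean()
        assert occupancy == pytest.approx(0.5, abs=0.02)

    def test_zero_off_rate_started_bound_is_absorbing(self):
        model = KineticSiteModel(k_on_per_conc=0.01, k_off=0.0, n_residues=2)
        series = simulate_contact_series(
            model, free_ligand=5.0, frames=500, seed=1, start_bound=True
        )
        assert series.residue_states.all()

    def test_stationary_occupancy_matches_isotherm(self):
        # binomial check with an effective sample size that accounts for the
        # chain's autocorrelation time
        model = KineticSiteModel(k_on_per_conc=0.05, k_off=0.2, n_residues=1)
        frames = 100_000
        free_ligand = 12.0
        p = model.stationary_occupancy(free_ligand)
        series = simulate_contact_series(model, free_ligand, frames, seed=11)
        observed = series.residue_states.mean()
        p_on, p_off = 0.05 * free_ligand, 0.2
        n_eff = frames / (1.0 / p_on + 1.0 / p_off)
        assert abs(observed - p) < 4 * math.sqrt(p * (1 - p) / n_eff)

    def test_transition_probability_above_one_errors(self):
        model = KineticSiteModel(k_on_per_conc=0.1, k_off=0.1)
        with pytest.raises(ValueError, match="probability"):
            simulate_contact_series(model, free_ligand=50.0, frames=10, seed=0)

    def test_determinism(self):
        model = KineticSiteModel(k_on_per_conc=0.01, k_off=0.1)
        a = simulate_contact_series(model, 10.0, 500, seed=42)
        b = simulate_contact_series(model, 10.0, 500, seed=42)
        np.testing.assert_array_equal(a.pair_states, b.pair_states)

    def test_emission_probability_thins_contacts(self):
        dense = KineticSiteModel(k_on_per_conc=0.05, k_off=0.05, n_residues=4)
        sparse = KineticSiteModel(
            k_on_per_conc=0.05, k_off=0.05, residue_emission_prob=0.3, n_residues=4
        )
        d = simulate_contact_series(dense, 10.0, 20_000, seed=9)
        s = simulate_contact_series(sparse, 10.0, 20_000, seed=9)
        assert s.pair_states.mean() < d.pair_states.mean()


class TestSaturationDataset:
    def test_points_lie_on_isotherm_at_scale(self):
        model = KineticSiteModel(k_on_per_conc=0.01, k_off=0.1)
        dataset, truth = generate_saturation_dataset(
            model, [1, 5, 10, 30], replicates=2, frames=30_000, base_seed=3
        )
        for point in dataset.points():
            expected = 100 * point.x / (truth["kd"] + point.x)
            assert point.y == pytest.approx(expected, abs=3.0)

    def test_identical_base_seed_is_bit_identical(self):
        model = KineticSiteModel(k_on_per_conc=0.01, k_off=0.1)
        a, _ = generate_saturation_dataset(model, [1, 5, 10], 2, 200, base_seed=7)
        b, _ = generate_saturation_dataset(model, [1, 5, 10], 2, 200, base_seed=7)
        for ea, eb in zip(a.entries, b.entries):
            np.testing.assert_array_equal(ea.residue_states, eb.residue_states)

    def test_duplicate_concentrations_rejected(self):
        model = KineticSiteModel(k_on_per_conc=0.01, k_off=0.1)
        with pytest.raises(ValueError, match="duplicate"):
            generate_saturation_dataset(model, [1, 1, 5], 2, 100, base_seed=0)

    def test_needs_three_concentrations(self):
        model = KineticSiteModel(k_on_per_conc=0.01, k_off=0.1)
        with pytest.raises(ValueError):
            generate_saturation_dataset(model, [1, 5], 2, 100, base_seed=0)


class TestSpatialEnsemble:
    def test_counts_conserved(self, small_spatial_system):
        model, system = small_spatial_system
        assert (
            system.molecules_of_species("CHOL").size == 2 * model.n_chol_per_leaflet
        )
        assert (
            system.molecules_of_species("POPC").size == 2 * model.n_popc_per_leaflet
        )

    def test_site_overlapping_protein_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SpatialEnsembleModel(
                site_regions=[
                    SiteRegion(center=(6.0, 6.0, 5.5), radius=0.5, well_depth=-5.0)
                ]
            )

    def test_positive_well_depth_rejected(self):
        with pytest.raises(ValueError, match="well depth"):
            SiteRegion(center=(9, 6, 5.5), radius=0.5, well_depth=2.0)

    def test_lipids_stay_in_membrane_slab(self, small_spatial_system):
        model, system = small_spatial_system
        z_lo, z_hi = model.membrane_z_bounds()
        lipid_beads = np.flatnonzero(system.bead_residue < 0)
        z = system.positions[:, lipid_beads, 2]
        assert z.min() >= z_lo and z.max() <= z_hi

    def test_flat_potential_is_uniform(self):
        model = SpatialEnsembleModel(
            site_regions=[
                SiteRegion(center=(9.0, 6.0, 5.5), radius=0.7, well_depth=0.0)
            ],
            n_chol_per_leaflet=40,
            n_popc_per_leaflet=40,
        )
        system = simulate_snapshot_ensemble(model, frames=400, seed=13)
        chol_beads = np.flatnonzero(
            np.isin(system.bead_to_molecule, system.molecules_of_species("CHOL"))
        )
        center = np.array([9.0, 6.0, 5.5])
        in_site = (
            np.linalg.norm(system.positions[:, chol_beads, :] - center, axis=2) < 0.7
        ).sum()
        region = model.site_regions[0]
        z = model.leaflet_z_bounds(1)
        slab_volume = (
            model.box[0] * model.box[1] - math.pi * model.protein_radius**2
        ) * (z[1] - z[0])
        expected = 400 * 40 * region.volume / slab_volume
        assert in_site == pytest.approx(expected, rel=0.25)

    def test_boltzmann_density_ratio(self):
        # -10 kJ/mol well at 310 K: site/bulk density ratio -> e^{10/RT} ~ 48.4
        region = SiteRegion(center=(8.6, 6.0, 5.5), radius=0.8, well_depth=-10.0)
        model = SpatialEnsembleModel(
            site_regions=[region], n_chol_per_leaflet=50, n_popc_per_leaflet=50
        )
        frames = 1000  # 1e5 cholesterol samples
        system = simulate_snapshot_ensemble(model, frames=frames, seed=17)
        chol_beads = np.flatnonzero(
            np.isin(system.bead_to_molecule, system.molecules_of_species("CHOL"))
        )
        xyz = system.positions[:, chol_beads, :].reshape(-1, 3)
        center = np.asarray(region.center)
        n_site = int((np.linalg.norm(xyz - center, axis=1) < region.radius).sum())
        z = model.leaflet_z_bounds(1)
        bulk_volume = (
            model.box[0] * model.box[1] * (z[1] - z[0])
            - math.pi * model.protein_radius**2 * (z[1] - z[0])
            - region.volume
        )
        n_bulk = frames * model.n_chol_per_leaflet - n_site
        ratio = (n_site / region.volume) / (n_bulk / bulk_volume)
        expected = math.exp(10.0 / (GAS_CONSTANT_KJ * 310.0))
        assert ratio == pytest.approx(expected, rel=0.1)

    def test_determinism(self):
        model = SpatialEnsembleModel(n_chol_per_leaflet=10, n_popc_per_leaflet=10)
        a = simulate_snapshot_ensemble(model, frames=5, seed=3)
        b = simulate_snapshot_ensemble(model, frames=5, seed=3)
        np.testing.assert_array_equal(a.positions, b.positions)
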