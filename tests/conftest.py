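import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spatial_system():
    """A small Boltzmann-enriched ensemble reused across modules."""
    from lipidsat.synthetic import SiteRegion, SpatialEnsembleModel, simulate_snapshot_ensemble

    # the site hugs the protein surface so most of its volume lies inside
    # the 0.8 nm "bound" shell, giving clear free-cholesterol depletion
    model = SpatialEnsembleModel(
        box=(12.0, 12.0, 9.0),
        protein_radius=1.2,
        site_regions=[SiteRegion(center=(7.7, 6.0, 5.5), radius=0.5, well_depth=-12.0)],
        n_chol_per_leaflet=30,
        n_popc_per_leaflet=45,
        temperature=310.0,
    )
    system = simulate_snapshot_ensemble(model, frames=50, seed=7)
    return model, system
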