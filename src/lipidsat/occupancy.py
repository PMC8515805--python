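"""Occupancy metrics and the free-ligand fraction.

Occupancy of a residue is the percentage of frames in which any tracked
lipid is in (dual-cutoff) contact with it; a site's occupancy is the mean
over its residues. The free-ligand fraction — unbound cholesterol as a
percentage of all unbound lipids — provides the abscissa of the binding
saturation curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from lipidsat.contacts import ContactSeries
from lipidsat.system import BeadSystem, SimulationCondition

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSION_DISTANCE = 0.8
NONSPECIFIC_BAND = (30.0, 50.0)


@dataclass(frozen=True)
class SiteDefinition:
    """A named binding site given as a list of (chain, resid) residues."""

    site_id: str
    residues: tuple[tuple[str, int], ...]

    def __init__(self, site_id: str, residues: Sequence[tuple[str, int]]):
        object.__setattr__(self, "site_id", str(site_id))
        object.__setattr__(
            self,
            "residues",
            tuple((str(c), int(r)) for c, r in residues),
        )
        if not self.residues:
            raise ValueError("a site needs at least one residue")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("site residues must be unique")

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OccupancyRecord:
    """One occupancy observation (percent of frames) with its provenance."""

    value: float
    condition: SimulationCondition
    site_id: str | None = None
    residue: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError("occupancy must lie in [0, 100] percent")


def residue_occupancy(series: ContactSeries, residue: tuple[str, int]) -> float:
    """Percent of frames with the residue in contact with any tracked lipid."""
    states = series.states_of(*residue)
    if states.size == 0:
        raise ValueError("contact series has zero frames")
    return 100.0 * float(np.count_nonzero(states)) / states.size


def site_occupancy(series: ContactSeries, site: SiteDefinition) -> float:
    """Mean of residue occupancies over the site's residues (percent)."""
    return float(
        np.mean([residue_occupancy(series, r) for r in site.residues])
    )


def nonspecific_residues(
    occupancies: Mapping[tuple[str, int], float],
    band: tuple[float, float] = NONSPECIFIC_BAND,
) -> set[tuple[str, int]]:
    """Residues whose occupancy lies in the closed band (default 30-50%).

    Computed at the reference composition (the highest cholesterol
    concentration simulated); the mean occupancy of the returned residues
    across conditions defines the nonspecific baseline curve. An empty
    selection is allowed but warned about.
    """
    lo, hi = band
    selected = {r for r, v in occupancies.items() if lo <= v <= hi}
    if not selected:
        warnings.warn(
            f"no residues with occupancy in the [{lo}, {hi}]% band; "
            "nonspecific baseline will be empty",
            stacklevel=2,
        )
    return selected


def unbound_lipid_counts(
    system: BeadSystem,
    ligand_species: str = "CHOL",
    background_species: Sequence[str] = ("POPC",),
    exclusion_distance: float = DEFAULT_EXCLUSION_DISTANCE,
) -> np.ndarray:
    """Per-frame counts of unbound ligand and background lipid molecules.

    A lipid is unbound in a frame iff the minimum distance from any of its
    beads to any protein bead exceeds ``exclusion_distance`` (nm), under
    periodic boundary conditions. Returns an (n_frames, 2) integer array of
    (unbound ligand, unbound background).
    """
    protein_beads = system.protein_bead_indices()
    if protein_beads.size == 0:
        raise ValueError("system contains no protein beads")
    ligand_ids = system.molecules_of_species(ligand_species)
    background_ids = np.concatenate(
        [system.molecules_of_species(s) for s in background_species]
    )
    if ligand_ids.size + background_ids.size == 0:
        raise ValueError("system contains no lipids to classify")

    lipid_ids = np.concatenate([ligand_ids, background_ids])
    is_ligand = np.concatenate(
        [np.ones(ligand_ids.size, bool), np.zeros(background_ids.size, bool)]
    )
    bead_lists = [system.beads_of_molecule(m) for m in lipid_ids]
    bead_idx = np.concatenate(bead_lists)
    bead_lipid = np.repeat(np.arange(lipid_ids.size), [len(b) for b in bead_lists])

    def _wrap(points: np.ndarray, box: np.ndarray) -> np.ndarray:
        wrapped = np.mod(points, box)
        wrapped[wrapped >= box] = 0.0  # float edge: mod can return exactly box
        return wrapped

    counts = np.zeros((system.n_frames, 2), dtype=int)
    for frame in range(system.n_frames):
        box = system.box[frame]
        # cKDTree with boxsize handles the periodic minimum image for
        # orthorhombic boxes; coordinates must be wrapped first.
        tree = cKDTree(_wrap(system.positions[frame][protein_beads], box), boxsize=box)
        dist, _ = tree.query(_wrap(system.positions[frame][bead_idx], box))
        min_per_lipid = np.full(lipid_ids.size, np.inf)
        np.minimum.at(min_per_lipid, bead_lipid, dist)
        unbound = min_per_lipid > exclusion_distance
        counts[frame, 0] = int(np.count_nonzero(unbound & is_ligand))
        counts[frame, 1] = int(np.count_nonzero(unbound & ~is_ligand))
    return counts


def free_ligand_fraction(
    system: BeadSystem,
    ligand_species: str = "CHOL",
    background_species: Sequence[str] = ("POPC",),
    exclusion_distance: float = DEFAULT_EXCLUSION_DISTANCE,
) -> float:
    """Free-ligand concentration in percent of all unbound lipids.

    Per frame, the fraction of unbound ligand molecules among all unbound
    lipids (ligand + background, same distance criterion for both); the
    result is 100 x the mean over frames. A frame with zero unbound lipids
    is an error.
    """
    counts = unbound_lipid_counts(
        system, ligand_species, background_species, exclusion_distance
    )
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"frame {bad} has zero unbound lipids")
    return 100.0 * float(np.mean(counts[:, 0] / totals))


def occupancy_table(
    series_by_condition: Mapping[SimulationCondition, ContactSeries],
    sites: Sequence[SiteDefinition],
    free_ligand_by_condition: Mapping[SimulationCondition, float] | None = None,
):
    """Tabulate per-replicate site occupancies (and free-ligand x values).

    Returns a pandas DataFrame with columns condition (mol% cholesterol),
    replicate, site_id, occupancy_percent and, when supplied,
    free_chol_percent.
    """
    import pandas as pd

    rows = []
    for condition, series in series_by_condition.items():
        for site in sites:
            row = {
                "condition": condition.total_cholesterol_percent,
                "replicate": condition.replicate_id,
                "site_id": site.site_id,
                "occupancy_percent": site_occupancy(series, site),
            }
            if free_ligand_by_condition is not None:
                row["free_chol_percent"] = free_ligand_by_condition[condition]
            rows.append(row)
    return pd.DataFrame(rows)
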