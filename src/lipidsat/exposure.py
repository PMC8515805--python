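"""Membrane exposure of a bound lipid: lipid vs protein contact fractions.

For each frame in which a site lipid is bound, beads of other lipids and of
the protein within a cutoff (default 0.6 nm) of any site-lipid bead are
counted; the exposure fraction is lipid / (lipid + protein), averaged over
bound frames. Solvent beads are not counted. A fraction near 0 indicates a
deeply buried lipid, near 1 a fully membrane-exposed one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from lipidsat.contacts import minimum_image_displacements
from lipidsat.saturation import replicate_sem
from lipidsat.system import BeadSystem

logger = logging.getLogger(__name__)

DEFAULT_EXPOSURE_CUTOFF = 0.6

LIPID_SPECIES = ("CHOL", "POPC", "other")


@dataclass
class ExposureResult:
    """Mean membrane-exposure fraction over the bound frames."""

    fraction: float
    frames_used: int
    sem: float = math.nan
    per_frame: list[tuple[int, int, int, float]] = field(default_factory=list)
    """(frame, lipid_contacts, protein_contacts, fraction) rows."""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("exposure fraction must lie in [0, 1]")
        if self.frames_used < 1:
            raise ValueError("at least one contributing frame is required")

    def to_frame_table(self):
        import pandas as pd

        return pd.DataFrame(
            self.per_frame,
            columns=["frame", "lipid_contacts", "protein_contacts", "fraction"],
        )


def membrane_exposure(
    system: BeadSystem,
    site_lipid: int,
    bound_frames: Iterable[int],
    cutoff: float = DEFAULT_EXPOSURE_CUTOFF,
    per_molecule: bool = False,
) -> ExposureResult:
    """Exposure fraction of one bound lipid molecule.

    Parameters
    ----------
    site_lipid : molecule id of the bound lipid.
    bound_frames : frames in which the lipid is considered bound to the site
        (supplied externally, e.g. from a contact series).
    cutoff : contact distance in nm (default 0.6).
    per_molecule : count contacting molecules instead of beads.

    Frames with zero total contacts contribute nothing and are logged; if
    every bound frame has zero contacts an error is raised.
    """
    bound_frames = sorted(set(int(f) for f in bound_frames))
    if not bound_frames:
        raise ValueError("bound_frames is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    site_beads = system.beads_of_molecule(site_lipid)
    if site_beads.size == 0:
        raise KeyError(f"no molecule with id {site_lipid}")
    species_of_bead = system.molecule_species[system.bead_to_molecule]
    is_lipid_bead = np.isin(species_of_bead, LIPID_SPECIES) & (
        system.bead_to_molecule != site_lipid
    )
    is_protein_bead = species_of_bead == "protein"
    other_idx = np.flatnonzero(is_lipid_bead | is_protein_bead)
    lipid_flag = is_lipid_bead[other_idx]
    molecule_of_other = system.bead_to_molecule[other_idx]

    per_frame: list[tuple[int, int, int, float]] = []
    fractions: list[float] = []
    for frame in bound_frames:
        delta = (
            system.positions[frame][other_idx][:, None, :]
            - system.positions[frame][site_beads][None, :, :]
        )
        delta = minimum_image_displacements(delta, system.box[frame])
        dist = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
        in_contact = (dist < cutoff).any(axis=1)
        if per_molecule:
            lipid_n = np.unique(molecule_of_other[in_contact & lipid_flag]).size
            protein_n = np.unique(molecule_of_other[in_contact & ~lipid_flag]).size
        else:
            lipid_n = int(np.count_nonzero(in_contact & lipid_flag))
            protein_n = int(np.count_nonzero(in_contact & ~lipid_flag))
        total = lipid_n + protein_n
        if total == 0:
            logger.info("frame %d: site lipid has no contacts; skipped", frame)
            continue
        fraction = lipid_n / total
        per_frame.append((frame, lipid_n, protein_n, fraction))
        fractions.append(fraction)

    if not fractions:
        raise ValueError("no bound frame had any lipid or protein contacts")
    return ExposureResult(
        fraction=float(np.mean(fractions)),
        frames_used=len(fractions),
        per_frame=per_frame,
    )


def exposure_sem(results: Sequence[ExposureResult]) -> float:
    """SEM of exposure fractions across replicate results."""
    return replicate_sem([r.fraction for r in results])
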