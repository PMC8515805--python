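"""Minimum-image distances and the dual-cutoff contact state machine.

A lipid-residue pair is "in contact" under a hysteresis rule: the contact
initiates when the minimum bead-bead distance drops below the lower cutoff
and persists until it exceeds the upper cutoff. This suppresses flicker at a
single threshold. Default cutoffs are 0.55 nm / 1.0 nm.

Distances are the minimum over all bead pairs of the two groups ("any bead
of the lipid against any bead of the residue"); no centre-of-mass shortcut
is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from lipidsat.system import BeadSystem, ResidueKey

DEFAULT_LOWER_CUTOFF = 0.55
DEFAULT_UPPER_CUTOFF = 1.0


@dataclass
class ContactSeries:
    """Boolean contact states per (lipid, residue) pair per frame.

    Attributes
    ----------
    pair_states : (n_lipids, n_residues, n_frames) bool array
    lipid_ids : (n_lipids,) int array of molecule ids
    residue_ids : list of (chain, resid) tuples
    lower_cutoff, upper_cutoff : float, nm
    """

    pair_states: np.ndarray
    lipid_ids: np.ndarray
    residue_ids: list[tuple[str, int]]
    lower_cutoff: float = DEFAULT_LOWER_CUTOFF
    upper_cutoff: float = DEFAULT_UPPER_CUTOFF

    def __post_init__(self) -> None:
        self.pair_states = np.asarray(self.pair_states, dtype=bool)
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=np.intp)
        self.residue_ids = [(str(c), int(r)) for c, r in self.residue_ids]
        if self.pair_states.ndim != 3:
            raise ValueError(
                "pair_states must have shape (n_lipids, n_residues, n_frames)"
            )
        if self.pair_states.shape[0] != self.lipid_ids.size:
            raise ValueError("lipid_ids length mismatch")
        if self.pair_states.shape[1] != len(self.residue_ids):
            raise ValueError("residue_ids length mismatch")
        if not 0 < self.lower_cutoff <= self.upper_cutoff:
            raise ValueError("need 0 < lower_cutoff <= upper_cutoff")

    @property
    def n_frames(self) -> int:
        return self.pair_states.shape[2]

    @property
    def residue_states(self) -> np.ndarray:
        """(n_residues, n_frames) bool: any tracked lipid in contact."""
        return self.pair_states.any(axis=0)

    def states_of(self, chain: str, resid: int) -> np.ndarray:
        """Per-frame contact state of one residue (OR over lipids)."""
        try:
            idx = self.residue_ids.index((str(chain), int(resid)))
        except ValueError:
            raise KeyError(
                f"residue ({chain!r}, {resid}) not tracked by this series"
            ) from None
        return self.residue_states[idx]

    @classmethod
    def concatenate(cls, first: "ContactSeries", second: "ContactSeries") -> "ContactSeries":
        """Join two windows of the same pairs along the frame axis."""
        if first.residue_ids != second.residue_ids or not np.array_equal(
            first.lipid_ids, second.lipid_ids
        ):
            raise ValueError("series track different lipid/residue pairs")
        return cls(
            pair_states=np.concatenate(
                [first.pair_states, second.pair_states], axis=2
            ),
            lipid_ids=first.lipid_ids,
            residue_ids=first.residue_ids,
            lower_cutoff=first.lower_cutoff,
            upper_cutoff=first.upper_cutoff,
        )

    def to_frame_table(self):
        """Long-format table: frame, chain, resid, state."""
        import pandas as pd

        states = self.residue_states
        records = []
        for (chain, resid), row in zip(self.residue_ids, states):
            for frame, state in enumerate(row):
                records.append((frame, chain, resid, bool(state)))
        return pd.DataFrame(records, columns=["frame", "chain", "resid", "state"])


def minimum_image_displacements(
    delta: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def min_bead_distance(
    group_a: np.ndarray, group_b: np.ndarray, box: np.ndarray
) -> float:
    """Minimum over all bead pairs of the minimum-image distance (nm).

    ``group_a`` and ``group_b`` are (n, 3) coordinate arrays; ``box`` holds
    the orthorhombic edge lengths.
    """
    group_a = np.atleast_2d(np.asarray(group_a, dtype=float))
    group_b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("bead groups must be non-empty")
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    delta = group_a[:, None, :] - group_b[None, :, :]
    delta = minimum_image_displacements(delta, box)
    return float(np.sqrt(np.min(np.einsum("ijk,ijk->ij", delta, delta))))


def dual_cutoff_states(
    distances: np.ndarray, lower: float, upper: float
) -> np.ndarray:
    """Hysteresis thresholding of a distance series.

    The state becomes true when distance < ``lower``, stays true while
    distance < ``upper``, and becomes false once distance >= ``upper``.
    Frame 0 is in contact iff its distance is already below ``lower`` — with
    no history, the hysteresis band is treated as out of contact.

    Accepts a 1D series or a (n_series, n_frames) batch; returns booleans of
    the same shape.
    """
    if lower > upper:
        raise ValueError("lower cutoff must not exceed upper cutoff")
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("distance series is empty")
    batch = np.atleast_2d(distances)
    below_lower = batch < lower
    below_upper = batch < upper
    states = np.empty_like(below_lower)
    states[:, 0] = below_lower[:, 0]
    for frame in range(1, batch.shape[1]):
        states[:, frame] = below_lower[:, frame] | (
            states[:, frame - 1] & below_upper[:, frame]
        )
    return states.reshape(distances.shape)


def pairwise_min_distances(
    positions: np.ndarray,
    groups_a: Sequence[np.ndarray],
    groups_b: Sequence[np.ndarray],
    box: np.ndarray,
) -> np.ndarray:
    """Min bead-bead distance for every (group_a, group_b) pair in one frame.

    Returns an (len(groups_a), len(groups_b)) array. Bead groups are index
    arrays into ``positions`` (one frame, shape (n_beads, 3)).
    """
    idx_a = np.concatenate(groups_a)
    idx_b = np.concatenate(groups_b)
    lab_a = np.repeat(np.arange(len(groups_a)), [len(g) for g in groups_a])
    lab_b = np.repeat(np.arange(len(groups_b)), [len(g) for g in groups_b])
    delta = positions[idx_a][:, None, :] - positions[idx_b][None, :, :]
    delta = minimum_image_displacements(delta, box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    out = np.full((len(groups_a), len(groups_b)), np.inf)
    np.minimum.at(out, (lab_a[:, None], lab_b[None, :]), dist)
    return out


def residue_contact_series(
    system: BeadSystem,
    species: str,
    residues: Sequence[tuple[str, int] | ResidueKey],
    lower: float = DEFAULT_LOWER_CUTOFF,
    upper: float = DEFAULT_UPPER_CUTOFF,
) -> ContactSeries:
    """Dual-cutoff contact states for every (lipid of ``species``, residue) pair.

    Per frame the minimum bead-bead minimum-image distance between each lipid
    molecule and each residue's beads feeds the hysteresis state machine.
    """
    residue_pairs = [(str(r[0]), int(r[1])) for r in residues]
    lipid_ids = system.molecules_of_species(species)
    if lipid_ids.size == 0:
        raise ValueError(f"no molecules of species {species!r} in system")
    lipid_groups = [system.beads_of_molecule(m) for m in lipid_ids]
    residue_groups = [system.beads_of_residue(c, r) for c, r in residue_pairs]

    n_frames = system.n_frames
    distances = np.empty((len(lipid_groups), len(residue_groups), n_frames))
    for frame in range(n_frames):
        distances[:, :, frame] = pairwise_min_distances(
            system.positions[frame], lipid_groups, residue_groups, system.box[frame]
        )
    flat = distances.reshape(-1, n_frames)
    states = dual_cutoff_states(flat, lower, upper).reshape(distances.shape)
    return ContactSeries(
        pair_states=states,
        lipid_ids=lipid_ids,
        residue_ids=residue_pairs,
        lower_cutoff=lower,
        upper_cutoff=upper,
    )
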