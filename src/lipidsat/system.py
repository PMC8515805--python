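"""Data model and I/O for coarse-grained bead systems and trajectories.

Coordinates are stored in nanometres internally regardless of the source
format (GRO files are nm natively; PDB files are converted from Angstrom).
Only orthorhombic boxes are supported; triclinic inputs are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from lipidsat.constants import SPECIES

logger = logging.getLogger(__name__)

_ANGSTROM_PER_NM = 10.0


class ResidueKey(NamedTuple):
    """Identifies a protein residue as a (chain, resid, resname) triple.

    Site lists are matched by chain + resid only; resname is carried for
    reporting. Multi-subunit proteins repeat resids across chains, so the
    chain is part of the identity.
    """

    chain: str
    resid: int
    resname: str = ""

    def matches(self, chain: str, resid: int) -> bool:
        return self.chain == chain and self.resid == resid


@dataclass
class TrajectoryWindow:
    """The set of frames an analysis operates over.

    Parameters
    ----------
    frame_times : array of float
        Time of each retained frame in ps, strictly increasing.
    frame_stride : int
        Stride applied when the frames were loaded.
    """

    frame_times: np.ndarray
    frame_stride: int = 1

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.ndim != 1 or self.frame_times.size < 1:
            raise ValueError("a trajectory window needs at least one frame")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")

    @property
    def frame_count(self) -> int:
        return int(self.frame_times.size)


@dataclass(frozen=True)
class SimulationCondition:
    """Bilayer composition and replicate label for one simulation."""

    total_cholesterol_percent: float
    replicate_id: int = 0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.total_cholesterol_percent <= 100.0:
            raise ValueError("cholesterol mol% must lie in [0, 100]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")


@dataclass
class BeadSystem:
    """Per-frame bead coordinates with molecule/species/residue mapping.

    Attributes
    ----------
    positions : (n_frames, n_beads, 3) float array, nm
    box : (n_frames, 3) float array, nm
        Orthorhombic box edge lengths per frame.
    bead_to_molecule : (n_beads,) int array
        Molecule id of each bead; ids index ``molecule_species``.
    molecule_species : (n_molecules,) str array
        One of :data:`lipidsat.constants.SPECIES` per molecule.
    bead_residue : (n_beads,) int array
        Index into ``residues`` for protein beads, -1 otherwise.
    residues : list of ResidueKey
        Protein residues in file order.
    """

    positions: np.ndarray
    box: np.ndarray
    bead_to_molecule: np.ndarray
    molecule_species: np.ndarray
    bead_residue: np.ndarray
    residues: list[ResidueKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.bead_to_molecule = np.asarray(self.bead_to_molecule, dtype=np.intp)
        self.molecule_species = np.asarray(self.molecule_species, dtype=object)
        self.bead_residue = np.asarray(self.bead_residue, dtype=np.intp)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_beads, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("coordinates contain non-finite values")
        if self.box.shape != (self.positions.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        n_beads = self.positions.shape[1]
        if self.bead_to_molecule.shape != (n_beads,):
            raise ValueError("bead_to_molecule must map every bead")
        if self.bead_to_molecule.min(initial=0) < 0 or (
            n_beads and self.bead_to_molecule.max() >= len(self.molecule_species)
        ):
            raise ValueError("bead_to_molecule references unknown molecules")
        unknown = set(self.molecule_species) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species labels: {sorted(unknown)}")
        if self.bead_residue.shape != (n_beads,):
            raise ValueError("bead_residue must cover every bead")
        protein_beads = self.molecule_species[self.bead_to_molecule] == "protein"
        if np.any(self.bead_residue[protein_beads] < 0):
            raise ValueError("every protein bead must map to a residue")

    # -- convenience selectors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_species)

    def molecules_of_species(self, species: str) -> np.ndarray:
        """Molecule ids whose species equals ``species``."""
        return np.flatnonzero(self.molecule_species == species)

    def beads_of_molecule(self, molecule_id: int) -> np.ndarray:
        return np.flatnonzero(self.bead_to_molecule == molecule_id)

    def protein_bead_indices(self) -> np.ndarray:
        return np.flatnonzero(
            self.molecule_species[self.bead_to_molecule] == "protein"
        )

    def beads_of_residue(self, chain: str, resid: int) -> np.ndarray:
        """Bead indices of the protein residue identified by chain + resid."""
        matches = [
            i for i, key in enumerate(self.residues) if key.matches(chain, resid)
        ]
        if not matches:
            raise KeyError(f"no protein residue with chain={chain!r} resid={resid}")
        mask = np.isin(self.bead_residue, matches)
        return np.flatnonzero(mask)

    def species_counts(self) -> dict[str, int]:
        """Molecule count per species; values sum to n_molecules."""
        return {s: int(np.sum(self.molecule_species == s)) for s in SPECIES}

    def take_frames(self, indices: np.ndarray | slice) -> "BeadSystem":
        """A view of the system restricted to the given frames."""
        return BeadSystem(
            positions=self.positions[indices],
            box=self.box[indices],
            bead_to_molecule=self.bead_to_molecule,
            molecule_species=self.molecule_species,
            bead_residue=self.bead_residue,
            residues=self.residues,
        )


def _require_orthorhombic(dimensions: np.ndarray, context: str) -> None:
    angles = dimensions[3:6]
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise ValueError(
            f"{context}: only orthorhombic boxes are supported "
            f"(got angles {angles.tolist()})"
        )


def load_system(
    coordinate_file: str | Path,
    trajectory_file: str | Path | None = None,
    species_map: Mapping[str, str] | None = None,
    stride: int = 1,
) -> tuple[BeadSystem, TrajectoryWindow]:
    """Read a coordinate file (GRO/PDB) plus optional trajectory (XTC/DCD).

    Parameters
    ----------
    coordinate_file, trajectory_file
        Paths understood by MDAnalysis. Without a trajectory the single
        coordinate frame is used.
    species_map
        Maps every residue name in the file to a species label from
        :data:`lipidsat.constants.SPECIES`. Residue names absent from the map
        raise ``KeyError``.
    stride
        Keep every ``stride``-th frame.

    Returns
    -------
    (BeadSystem, TrajectoryWindow)
    """
    import MDAnalysis as mda

    if species_map is None:
        raise ValueError("a species_map is required")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    coordinate_file = Path(coordinate_file)
    if not coordinate_file.exists():
        raise FileNotFoundError(coordinate_file)
    if trajectory_file is not None:
        trajectory_file = Path(trajectory_file)
        if not trajectory_file.exists():
            raise FileNotFoundError(trajectory_file)
        universe = mda.Universe(str(coordinate_file), str(trajectory_file))
    else:
        universe = mda.Universe(str(coordinate_file))

    bad = {str(r) for r in universe.residues.resnames} - set(species_map)
    if bad:
        raise KeyError(
            f"residue name(s) not in species_map: {sorted(bad)}"
        )
    for name, label in species_map.items():
        if label not in SPECIES:
            raise ValueError(
                f"species_map maps {name!r} to unknown species {label!r}"
            )

    residue_species = np.array(
        [species_map[str(r)] for r in universe.residues.resnames], dtype=object
    )
    resindices = universe.atoms.resindices

    # Molecule assignment: protein residues of one segment form one molecule;
    # every non-protein residue is its own molecule.
    n_res = len(universe.residues)
    molecule_of_residue = np.full(n_res, -1, dtype=np.intp)
    molecule_species_list: list[str] = []
    seg_molecule: dict[int, int] = {}
    for ridx in range(n_res):
        spec = residue_species[ridx]
        if spec == "protein":
            seg = universe.residues[ridx].segindex
            if seg not in seg_molecule:
                seg_molecule[seg] = len(molecule_species_list)
                molecule_species_list.append("protein")
            molecule_of_residue[ridx] = seg_molecule[seg]
        else:
            molecule_of_residue[ridx] = len(molecule_species_list)
            molecule_species_list.append(spec)

    residues: list[ResidueKey] = []
    residue_index_of = np.full(n_res, -1, dtype=np.intp)
    for ridx in range(n_res):
        if residue_species[ridx] == "protein":
            res = universe.residues[ridx]
            chain = str(res.segid).strip() or "A"
            residue_index_of[ridx] = len(residues)
            residues.append(ResidueKey(chain, int(res.resid), str(res.resname)))

    bead_to_molecule = molecule_of_residue[resindices]
    bead_residue = residue_index_of[resindices]

    frames: list[np.ndarray] = []
    boxes: list[np.ndarray] = []
    times: list[float] = []
    for ts in universe.trajectory[::stride]:
        _require_orthorhombic(np.asarray(ts.dimensions, dtype=float), coordinate_file.name)
        frames.append(universe.atoms.positions.astype(float) / _ANGSTROM_PER_NM)
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / _ANGSTROM_PER_NM)
        times.append(float(ts.time))
    if not frames:
        raise ValueError("trajectory contains zero frames after striding")

    times_arr = np.asarray(times, dtype=float)
    if times_arr.size > 1 and np.any(np.diff(times_arr) <= 0):
        # Some writers emit all-zero times; fall back to frame indices.
        times_arr = np.arange(times_arr.size, dtype=float)

    system = BeadSystem(
        positions=np.stack(frames),
        box=np.stack(boxes),
        bead_to_molecule=bead_to_molecule,
        molecule_species=np.array(molecule_species_list, dtype=object),
        bead_residue=bead_residue,
        residues=residues,
    )
    window = TrajectoryWindow(frame_times=times_arr, frame_stride=stride)
    logger.info(
        "loaded %d beads, %d molecules, %d frames from %s",
        system.n_beads,
        system.n_molecules,
        window.frame_count,
        coordinate_file.name,
    )
    return system, window


def truncate_window(window: TrajectoryWindow, max_time: float) -> TrajectoryWindow:
    """Retain only frames with time <= ``max_time`` (ps).

    Raises ``ValueError`` if ``max_time`` falls below the first frame time.
    """
    if max_time <= 0:
        raise ValueError("max_time must be positive")
    keep = window.frame_times <= max_time
    if not keep.any():
        raise ValueError(
            f"max_time {max_time} ps is before the first frame "
            f"({window.frame_times[0]} ps)"
        )
    return TrajectoryWindow(
        frame_times=window.frame_times[keep], frame_stride=window.frame_stride
    )


def _build_universe(system: BeadSystem):
    """Construct an MDAnalysis Universe mirroring the bead system topology."""
    import MDAnalysis as mda

    resindex_of_bead = np.zeros(system.n_beads, dtype=np.intp)
    resnames: list[str] = []
    resids: list[int] = []
    res_lookup: dict[tuple, int] = {}
    for bead in range(system.n_beads):
        ridx = system.bead_residue[bead]
        if ridx >= 0:
            key = ("res", int(ridx))
            name = system.residues[ridx].resname or "BB"
            rid = system.residues[ridx].resid
        else:
            mol = int(system.bead_to_molecule[bead])
            key = ("mol", mol)
            spec = system.molecule_species[mol]
            name = {"CHOL": "CHOL", "POPC": "POPC", "solvent": "W"}.get(spec, "OTH")
            rid = mol + 1
        if key not in res_lookup:
            res_lookup[key] = len(resnames)
            resnames.append(name)
            resids.append(rid)
        resindex_of_bead[bead] = res_lookup[key]

    universe = mda.Universe.empty(
        n_atoms=system.n_beads,
        n_residues=len(resnames),
        atom_resindex=resindex_of_bead,
        trajectory=True,
    )
    universe.add_TopologyAttr("resnames", resnames)
    universe.add_TopologyAttr("resids", resids)
    universe.add_TopologyAttr("names", ["B"] * system.n_beads)
    return universe


def write_gro(system: BeadSystem, frame: int, path: str | Path) -> None:
    """Write one frame as a GRO file (nm, 3 decimal places)."""
    universe = _build_universe(system)
    universe.atoms.positions = system.positions[frame] * _ANGSTROM_PER_NM
    universe.dimensions = np.concatenate(
        [system.box[frame] * _ANGSTROM_PER_NM, [90.0, 90.0, 90.0]]
    )
    universe.atoms.write(str(path))


def write_trajectory(
    system: BeadSystem,
    gro_path: str | Path,
    traj_path: str | Path,
    frame_times: Sequence[float] | None = None,
) -> None:
    """Write the full system as GRO (first frame) + DCD trajectory."""
    import MDAnalysis as mda

    write_gro(system, 0, gro_path)
    universe = _build_universe(system)
    with mda.Writer(str(traj_path), n_atoms=system.n_beads) as writer:
        for f in range(system.n_frames):
            universe.atoms.positions = system.positions[f] * _ANGSTROM_PER_NM
            universe.dimensions = np.concatenate(
                [system.box[f] * _ANGSTROM_PER_NM, [90.0, 90.0, 90.0]]
            )
            universe.trajectory.ts.frame = f
            if frame_times is not None:
                universe.trajectory.ts.time = float(frame_times[f])
            writer.write(universe.atoms)
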