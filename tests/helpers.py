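"""Hand-rolled builders and independent oracles shared by the test modules.

The oracles here deliberately re-derive results with the most naive
formulation possible (triple loops, explicit minimum-image arithmetic,
literal state machines) so that they stay independent of the library code
they check.
"""

from __future__ import annotations

import math

import numpy as np

from lipidsat.system import BeadSystem, ResidueKey


def build_system(
    frames: list[dict],
    box: tuple[float, float, float] = (10.0, 10.0, 10.0),
) -> BeadSystem:
    """Construct a BeadSystem from explicit per-frame molecule coordinates.

    ``frames`` is a list of dicts mapping molecule label -> (n_beads, 3)
    coordinates; labels are '<species>:<index>' e.g. 'CHOL:0'. Protein beads
    get one residue each: ('A', bead_ordinal + 1).
    """
    labels = list(frames[0].keys())
    species_of = [label.split(":")[0] for label in labels]
    n_mol = len(labels)

    bead_to_molecule = []
    for mol_idx, label in enumerate(labels):
        n_beads = np.atleast_2d(np.asarray(frames[0][label])).shape[0]
        bead_to_molecule.extend([mol_idx] * n_beads)
    bead_to_molecule = np.asarray(bead_to_molecule, dtype=np.intp)

    positions = np.stack(
        [
            np.concatenate([np.atleast_2d(np.asarray(f[label], float)) for label in labels])
            for f in frames
        ]
    )

    residues: list[ResidueKey] = []
    bead_residue = np.full(positions.shape[1], -1, dtype=np.intp)
    bead = 0
    for mol_idx, label in enumerate(labels):
        n_beads = np.atleast_2d(np.asarray(frames[0][label])).shape[0]
        if species_of[mol_idx] == "protein":
            for _ in range(n_beads):
                bead_residue[bead] = len(residues)
                residues.append(ResidueKey("A", len(residues) + 1, "BB"))
                bead += 1
        else:
            bead += n_beads
    return BeadSystem(
        positions=positions,
        box=np.tile(np.asarray(box, float), (len(frames), 1)),
        bead_to_molecule=bead_to_molecule,
        molecule_species=np.array(species_of, dtype=object),
        bead_residue=bead_residue,
        residues=residues,
    )


def brute_force_min_distance(group_a, group_b, box) -> float:
    """Exhaustive O(N^2) minimum-image pairwise minimum, scalar arithmetic."""
    best = math.inf
    for a in np.atleast_2d(group_a):
        for b in np.atleast_2d(group_b):
            total = 0.0
            for d in range(3):
                delta = a[d] - b[d]
                delta -= box[d] * round(delta / box[d])
                total += delta * delta
            best = min(best, math.sqrt(total))
    return best


def hand_hysteresis(distances, lower, upper) -> list[bool]:
    """Literal transcription of the dual-cutoff rule."""
    states = []
    current = False
    for i, d in enumerate(distances):
        if i == 0:
            current = d < lower
        elif d < lower:
            current = True
        elif d >= upper:
            current = False
        # else: keep previous state (inside the hysteresis band)
        states.append(current)
    return states


def oracle_contact_states(system: BeadSystem, species, residue_pairs, lower, upper):
    """Naive per-frame re-evaluation of the full contact pipeline."""
    lipid_ids = [
        m for m in range(system.n_molecules) if system.molecule_species[m] == species
    ]
    out = np.zeros((len(lipid_ids), len(residue_pairs), system.n_frames), dtype=bool)
    for li, mol in enumerate(lipid_ids):
        lipid_beads = [b for b in range(system.n_beads) if system.bead_to_molecule[b] == mol]
        for ri, (chain, resid) in enumerate(residue_pairs):
            res_beads = [
                b
                for b in range(system.n_beads)
                if system.bead_residue[b] >= 0
                and system.residues[system.bead_residue[b]].chain == chain
                and system.residues[system.bead_residue[b]].resid == resid
            ]
            dists = [
                brute_force_min_distance(
                    system.positions[f][lipid_beads],
                    system.positions[f][res_beads],
                    system.box[f],
                )
                for f in range(system.n_frames)
            ]
            out[li, ri] = hand_hysteresis(dists, lower, upper)
    return out


def random_toy_system(rng: np.random.Generator) -> BeadSystem:
    """A randomized <=50 bead, <=20 frame system with protein + CHOL lipids."""
    n_frames = int(rng.integers(2, 21))
    n_residues = int(rng.integers(1, 5))
    beads_per_residue = int(rng.integers(1, 3))
    n_lipids = int(rng.integers(1, 4))
    beads_per_lipid = int(rng.integers(1, 4))
    box_len = float(rng.uniform(3.0, 6.0))
    box = (box_len, box_len, box_len)

    frames = []
    for _ in range(n_frames):
        frame = {}
        frame["protein:0"] = rng.uniform(0, box_len, size=(n_residues * beads_per_residue, 3))
        for li in range(n_lipids):
            frame[f"CHOL:{li}"] = rng.uniform(0, box_len, size=(beads_per_lipid, 3))
        frames.append(frame)

    system = build_system(frames, box=box)
    # group protein beads into n_residues residues of beads_per_residue each
    residues = [ResidueKey("A", r + 1, "BB") for r in range(n_residues)]
    bead_residue = system.bead_residue.copy()
    protein_beads = system.protein_bead_indices()
    for i, b in enumerate(protein_beads):
        bead_residue[b] = i // beads_per_residue
    return BeadSystem(
        positions=system.positions,
        box=system.box,
        bead_to_molecule=system.bead_to_molecule,
        molecule_species=system.molecule_species,
        bead_residue=bead_residue,
        residues=residues,
    )
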