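"""Ground-truth synthetic generators for validating every analysis stage.

Two generators are provided:

* a two-state Markov (empty <-> bound) kinetic model whose stationary
  occupancy follows the one-site isotherm with a known dissociation
  constant, emitting per-residue contact series; and
* an equilibrium spatial ensemble of single-bead lipids around a static
  cylindrical protein proxy, with Boltzmann-weighted enrichment inside
  spherical site regions of known well depth.

Both are deterministic given a seed, so parameter-recovery tests are exact
to Monte-Carlo error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from lipidsat.constants import GAS_CONSTANT_KJ
from lipidsat.contacts import ContactSeries
from lipidsat.saturation import SaturationDataset
from lipidsat.system import BeadSystem, ResidueKey, SimulationCondition


@dataclass(frozen=True)
class KineticSiteModel:
    """Two-state binding kinetics with a known dissociation constant.

    Transition probabilities per frame are ``k_on_per_conc * [L]`` (empty ->
    bound) and ``k_off`` (bound -> empty), so the stationary bound
    probability is [L] / (Kd + [L]) with Kd = k_off / k_on_per_conc. While
    bound, each site residue independently registers a contact with
    probability ``residue_emission_prob``.
    """

    k_on_per_conc: float
    k_off: float
    residue_emission_prob: float = 1.0
    n_residues: int = 6

    def __post_init__(self) -> None:
        if self.k_on_per_conc < 0 or self.k_off < 0:
            raise ValueError("rates must be non-negative")
        if self.k_on_per_conc == 0:
            raise ValueError("k_on_per_conc must be positive for a finite Kd")
        if not 0 < self.residue_emission_prob <= 1:
            raise ValueError("emission probability must lie in (0, 1]")
        if self.n_residues < 1:
            raise ValueError("need at least one site residue")

    @property
    def ground_truth_kd(self) -> float:
        """Kd in the same concentration units as the driving [L] (percent)."""
        return self.k_off / self.k_on_per_conc

    def stationary_occupancy(self, free_ligand: float) -> float:
        """Bound-state probability [L] / (Kd + [L])."""
        return free_ligand / (self.ground_truth_kd + free_ligand)


def simulate_contact_series(
    model: KineticSiteModel,
    free_ligand: float,
    frames: int,
    seed: int | np.random.SeedSequence,
    start_bound: bool | None = None,
) -> ContactSeries:
    """Simulate the two-state chain and emit a per-residue contact series.

    ``start_bound=None`` draws the initial state from the stationary
    distribution. The returned series has one tracked "lipid" and
    ``model.n_residues`` residues labelled ("A", 1..n).
    """
    if frames < 1:
        raise ValueError("frames must be >= 1")
    if free_ligand < 0:
        raise ValueError("free_ligand must be >= 0")
    p_on = model.k_on_per_conc * free_ligand
    p_off = model.k_off
    if p_on > 1 or p_off > 1:
        raise ValueError(
            f"per-frame transition probability exceeds 1 (p_on={p_on:.3g}, "
            f"p_off={p_off:.3g}); reduce rates or concentration"
        )
    rng = np.random.default_rng(seed)
    if start_bound is None:
        total = p_on + p_off
        p_stationary = p_on / total if total > 0 else 0.0
        state = bool(rng.random() < p_stationary)
    else:
        state = bool(start_bound)

    uniforms = rng.random(frames)
    bound = np.empty(frames, dtype=bool)
    for t in range(frames):
        if state:
            if uniforms[t] < p_off:
                state = False
        else:
            if uniforms[t] < p_on:
                state = True
        bound[t] = state

    if model.residue_emission_prob >= 1.0:
        contacts = np.broadcast_to(bound, (model.n_residues, frames)).copy()
    else:
        emit = rng.random((model.n_residues, frames)) < model.residue_emission_prob
        contacts = emit & bound[None, :]

    return ContactSeries(
        pair_states=contacts[None, :, :],
        lipid_ids=np.array([0]),
        residue_ids=[("A", i + 1) for i in range(model.n_residues)],
    )


def generate_saturation_dataset(
    model: KineticSiteModel,
    concentrations: Sequence[float],
    replicates: int,
    frames: int,
    base_seed: int,
    site_id: str = "site",
) -> tuple[SaturationDataset, dict]:
    """Simulate a full saturation experiment with known ground truth.

    One contact series per (concentration, replicate); the per-series seed is
    ``SeedSequence(base_seed, spawn_key=(conc_index, replicate))``, so
    replicates are independent yet the whole dataset is reproducible from
    ``base_seed`` alone.

    Returns the dataset (with raw bound-state series, enabling truncation
    scans) and a ground-truth dict with the model Kd and plateau.
    """
    concentrations = [float(c) for c in concentrations]
    if len(concentrations) < 3:
        raise ValueError("need at least 3 concentrations")
    if len(set(concentrations)) != len(concentrations):
        raise ValueError("duplicate concentrations would reuse seeds")
    if replicates < 1:
        raise ValueError("need at least one replicate")

    dataset = SaturationDataset(site_id=site_id)
    for ci, conc in enumerate(concentrations):
        for rep in range(replicates):
            seed = np.random.SeedSequence(base_seed, spawn_key=(ci, rep))
            series = simulate_contact_series(model, conc, frames, seed)
            condition = SimulationCondition(
                total_cholesterol_percent=min(conc, 100.0), replicate_id=rep
            )
            dataset.add(conc, series.residue_states, condition)
    ground_truth = {
        "kd": model.ground_truth_kd,
        "bmax": 100.0 * model.residue_emission_prob,
    }
    return dataset, ground_truth


@dataclass(frozen=True)
class SiteRegion:
    """Spherical enrichment region with a (non-positive) well depth in kJ/mol."""

    center: tuple[float, float, float]
    radius: float
    well_depth: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("site radius must be positive")
        if self.well_depth > 0:
            raise ValueError("well depth must be <= 0 (attractive or flat)")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass
class SpatialEnsembleModel:
    """Static protein proxy in a slab membrane with Boltzmann site enrichment.

    The membrane occupies z in [center_z - membrane_half_thickness,
    center_z + membrane_half_thickness]; the two leaflets split at center_z.
    The protein proxy is a cylinder of beads on the box axis. Cholesterol is
    placed i.i.d. per frame from exp(-U/RT) with U = well_depth inside site
    spheres and 0 elsewhere; the background lipid (POPC) is uniform. Each
    lipid is a single bead.
    """

    box: tuple[float, float, float] = (12.0, 12.0, 9.0)
    protein_radius: float = 1.2
    membrane_half_thickness: float = 2.0
    site_regions: list[SiteRegion] = field(default_factory=list)
    n_chol_per_leaflet: int = 50
    n_popc_per_leaflet: int = 100
    temperature: float = 310.0
    protein_bead_spacing: float = 0.3

    def __post_init__(self) -> None:
        if self.n_chol_per_leaflet <= 0 or self.n_popc_per_leaflet <= 0:
            raise ValueError("lipid counts must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        box = np.asarray(self.box, float)
        axis = box[:2] / 2.0
        z_lo = box[2] / 2.0 - self.membrane_half_thickness
        z_hi = box[2] / 2.0 + self.membrane_half_thickness
        for region in self.site_regions:
            center = np.asarray(region.center, float)
            radial = float(np.hypot(*(center[:2] - axis)))
            if radial < self.protein_radius + region.radius:
                raise ValueError(
                    f"site region at {region.center} overlaps the protein proxy"
                )
            if not (z_lo <= center[2] - region.radius and center[2] + region.radius <= z_hi):
                raise ValueError(
                    f"site region at {region.center} must sit fully inside a leaflet slab"
                )
            if np.any(center - region.radius < 0) or np.any(center + region.radius > box):
                raise ValueError("site region extends outside the box")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KJ * self.temperature

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.box, float) / 2.0

    def membrane_z_bounds(self) -> tuple[float, float]:
        zc = self.box[2] / 2.0
        return zc - self.membrane_half_thickness, zc + self.membrane_half_thickness

    def leaflet_z_bounds(self, leaflet: int) -> tuple[float, float]:
        """z bounds of leaflet 0 (lower) or 1 (upper)."""
        z_lo, z_hi = self.membrane_z_bounds()
        zc = self.box[2] / 2.0
        return (z_lo, zc) if leaflet == 0 else (zc, z_hi)

    def protein_bead_positions(self) -> np.ndarray:
        """Beads on the proxy cylinder surface plus its axis."""
        z_lo, z_hi = self.membrane_z_bounds()
        spacing = self.protein_bead_spacing
        z_levels = np.arange(z_lo, z_hi + 1e-9, spacing)
        n_ring = max(6, int(round(2 * math.pi * self.protein_radius / spacing)))
        angles = np.linspace(0.0, 2 * math.pi, n_ring, endpoint=False)
        cx, cy = self.center[:2]
        beads = []
        for z in z_levels:
            beads.append(
                np.column_stack(
                    [
                        cx + self.protein_radius * np.cos(angles),
                        cy + self.protein_radius * np.sin(angles),
                        np.full(n_ring, z),
                    ]
                )
            )
            beads.append(np.array([[cx, cy, z]]))
        return np.concatenate(beads)


def _sample_in_ball(
    rng: np.random.Generator, center: np.ndarray, radius: float, n: int
) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return center + direction * r[:, None]


def _sample_slab_excluding(
    rng: np.random.Generator,
    model: SpatialEnsembleModel,
    z_bounds: tuple[float, float],
    n: int,
    exclude_sites: Sequence[SiteRegion],
) -> np.ndarray:
    """Uniform points in the leaflet slab outside the protein cylinder and sites."""
    box = np.asarray(model.box, float)
    axis = model.center[:2]
    out = np.empty((0, 3))
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 64)
        cand = np.column_stack(
            [
                rng.random(m) * box[0],
                rng.random(m) * box[1],
                z_bounds[0] + rng.random(m) * (z_bounds[1] - z_bounds[0]),
            ]
        )
        ok = np.hypot(*(cand[:, :2] - axis).T) > model.protein_radius
        for region in exclude_sites:
            center = np.asarray(region.center)
            ok &= np.linalg.norm(cand - center, axis=1) > region.radius
        out = np.concatenate([out, cand[ok]])
    return out[:n]


def simulate_snapshot_ensemble(
    model: SpatialEnsembleModel,
    frames: int,
    seed: int | np.random.SeedSequence = 0,
) -> BeadSystem:
    """Sample an equilibrium bead ensemble with known site free energies.

    Cholesterol positions are drawn i.i.d. per frame from the Boltzmann
    weight exp(-U/RT): a site sphere of well depth dG* is chosen with
    probability proportional to V_site * exp(-dG*/RT) against the remaining
    leaflet volume, so the site/bulk density ratio converges to
    exp(-dG*/RT). POPC is uniform in each leaflet. The protein proxy is
    static.
    """
    if frames < 1:
        raise ValueError("frames must be >= 1")
    rng = np.random.default_rng(seed)
    box = np.asarray(model.box, float)
    protein_xyz = model.protein_bead_positions()
    n_protein = protein_xyz.shape[0]

    leaflet_sites: list[list[SiteRegion]] = [[], []]
    for region in model.site_regions:
        zc = box[2] / 2.0
        leaflet_sites[0 if region.center[2] < zc else 1].append(region)

    chol_xyz = np.empty((frames, 2 * model.n_chol_per_leaflet, 3))
    popc_xyz = np.empty((frames, 2 * model.n_popc_per_leaflet, 3))
    for leaflet in (0, 1):
        z_bounds = model.leaflet_z_bounds(leaflet)
        sites = leaflet_sites[leaflet]
        slab_volume = (
            box[0] * box[1] * (z_bounds[1] - z_bounds[0])
            - math.pi * model.protein_radius**2 * (z_bounds[1] - z_bounds[0])
        )
        bulk_volume = slab_volume - sum(s.volume for s in sites)
        weights = np.array(
            [bulk_volume] + [s.volume * math.exp(-s.well_depth / model.rt) for s in sites]
        )
        probs = weights / weights.sum()

        n_chol = frames * model.n_chol_per_leaflet
        category = rng.choice(len(weights), size=n_chol, p=probs)
        positions = np.empty((n_chol, 3))
        bulk_sel = category == 0
        positions[bulk_sel] = _sample_slab_excluding(
            rng, model, z_bounds, int(bulk_sel.sum()), sites
        )
        for k, region in enumerate(sites, start=1):
            sel = category == k
            positions[sel] = _sample_in_ball(
                rng, np.asarray(region.center), region.radius, int(sel.sum())
            )
        sl = slice(
            leaflet * model.n_chol_per_leaflet, (leaflet + 1) * model.n_chol_per_leaflet
        )
        chol_xyz[:, sl, :] = positions.reshape(frames, model.n_chol_per_leaflet, 3)

        n_popc = frames * model.n_popc_per_leaflet
        popc_positions = _sample_slab_excluding(rng, model, z_bounds, n_popc, [])
        sp = slice(
            leaflet * model.n_popc_per_leaflet, (leaflet + 1) * model.n_popc_per_leaflet
        )
        popc_xyz[:, sp, :] = popc_positions.reshape(frames, model.n_popc_per_leaflet, 3)

    n_chol_total = 2 * model.n_chol_per_leaflet
    n_popc_total = 2 * model.n_popc_per_leaflet
    positions = np.concatenate(
        [
            np.broadcast_to(protein_xyz, (frames, n_protein, 3)),
            chol_xyz,
            popc_xyz,
        ],
        axis=1,
    )

    bead_to_molecule = np.concatenate(
        [
            np.zeros(n_protein, dtype=np.intp),
            1 + np.arange(n_chol_total),
            1 + n_chol_total + np.arange(n_popc_total),
        ]
    )
    molecule_species = np.array(
        ["protein"] + ["CHOL"] * n_chol_total + ["POPC"] * n_popc_total, dtype=object
    )
    residues = [ResidueKey("P", i + 1, "BB") for i in range(n_protein)]
    bead_residue = np.concatenate(
        [
            np.arange(n_protein, dtype=np.intp),
            np.full(n_chol_total + n_popc_total, -1, dtype=np.intp),
        ]
    )
    return BeadSystem(
        positions=positions,
        box=np.tile(box, (frames, 1)),
        bead_to_molecule=bead_to_molecule,
        molecule_species=molecule_species,
        bead_residue=bead_residue,
        residues=residues,
    )
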