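"""3D voxel densities of lipid beads and density-ratio binding free energies.

Selected bead positions are accumulated on a fixed rectangular grid (default
0.1 nm bins) centred on the protein transmembrane region. The binding free
energy of a site is obtained by comparing the mean density inside a site
mask to the mean density in a bulk-membrane mask:

    dG = -RT ln(rho_site / rho_bulk)

Frames can be aligned to the first frame by superposing the protein beads
(translation plus rotation about the membrane normal) before accumulation,
so that site density does not smear as the protein diffuses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from lipidsat.constants import GAS_CONSTANT_KJ
from lipidsat.system import BeadSystem

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 0.1


@dataclass
class DensityGrid:
    """Voxel counts on a rectangular grid.

    Attributes
    ----------
    counts : (nx, ny, nz) int array
    edges : tuple of three 1D arrays — bin edges (nm) along x, y, z.
    bin_size : float, nm
    center : (3,) array — grid centre in system coordinates (nm).
    samples : int — total bead-frames counted (== counts.sum()).
    """

    counts: np.ndarray
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    bin_size: float
    center: np.ndarray
    samples: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if int(self.counts.sum()) != int(self.samples):
            raise ValueError("samples must equal the sum of voxel counts")

    @property
    def voxel_volume(self) -> float:
        return float(
            np.prod([np.diff(e).mean() for e in self.edges])
        )

    @property
    def density(self) -> np.ndarray:
        """Probability density per voxel: counts / (samples * voxel volume)."""
        if self.samples == 0:
            raise ValueError("grid holds no samples")
        return self.counts / (self.samples * self.voxel_volume)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    def export_dx(self, path: str | Path) -> None:
        """Write the density as an OpenDX file (gridDataFormats)."""
        from gridData import Grid

        origin = [float(e[0] + 0.5 * self.bin_size) for e in self.edges]
        grid = Grid(
            self.density,
            origin=origin,
            delta=[self.bin_size] * 3,
        )
        grid.export(str(path), file_format="dx")


@dataclass
class RegionMask:
    """Boolean voxel selection over a DensityGrid (site or bulk)."""

    mask: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ("site", "bulk"):
            raise ValueError("mask kind must be 'site' or 'bulk'")
        if not self.mask.any():
            raise ValueError(f"{self.kind} mask selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _align_rotation_z(ref_xy: np.ndarray, cur_xy: np.ndarray) -> float:
    """Optimal rotation angle about z superposing cur onto ref (centred)."""
    num = float(np.sum(cur_xy[:, 0] * ref_xy[:, 1] - cur_xy[:, 1] * ref_xy[:, 0]))
    den = float(np.sum(cur_xy[:, 0] * ref_xy[:, 0] + cur_xy[:, 1] * ref_xy[:, 1]))
    return math.atan2(num, den)


def aligned_positions(system: BeadSystem, align: bool = True) -> np.ndarray:
    """Positions with each frame superposed onto frame 0 via the protein.

    The transform is a translation of the protein centre of mass plus a
    rotation about z (the bilayer normal breaks full rotational symmetry).
    With ``align=False`` raw positions are returned.
    """
    if not align:
        return system.positions
    protein = system.protein_bead_indices()
    if protein.size == 0:
        raise ValueError("cannot align: system has no protein beads")
    ref = system.positions[0][protein]
    ref_com = ref.mean(axis=0)
    ref_centered = ref - ref_com
    out = np.empty_like(system.positions)
    for frame in range(system.n_frames):
        cur = system.positions[frame][protein]
        cur_com = cur.mean(axis=0)
        theta = _align_rotation_z(ref_centered[:, :2], (cur - cur_com)[:, :2])
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        out[frame] = (system.positions[frame] - cur_com) @ rot.T + ref_com
    return out


def accumulate_density(
    system: BeadSystem,
    selection: np.ndarray,
    center: np.ndarray | None = None,
    extents: Sequence[float] = (10.0, 10.0, 10.0),
    bin_size: float = DEFAULT_BIN_SIZE,
    align: bool = True,
) -> DensityGrid:
    """Histogram selected bead positions over all frames onto a 3D grid.

    Parameters
    ----------
    selection : bead index array (e.g. all CHOL beads).
    center : grid centre (nm); defaults to the protein centre of mass in
        frame 0 — the paper's protein-TMD-centred convention.
    extents : grid edge lengths (nm) along x, y, z.
    bin_size : voxel edge (nm), default 0.1.
    align : superpose frames on the protein before binning.

    Beads falling outside the grid are not counted; ``samples`` reflects only
    in-grid bead-frames.
    """
    selection = np.asarray(selection, dtype=np.intp)
    if selection.size == 0:
        raise ValueError("selection is empty")
    if system.n_frames == 0:
        raise ValueError("system has zero frames")
    positions = aligned_positions(system, align=align)
    if center is None:
        protein = system.protein_bead_indices()
        if protein.size == 0:
            raise ValueError("no protein beads to centre the grid on")
        center = positions[0][protein].mean(axis=0)
    center = np.asarray(center, dtype=float)
    extents = np.asarray(extents, dtype=float)
    nbins = np.maximum(1, np.round(extents / bin_size).astype(int))
    edges = tuple(
        center[d] - extents[d] / 2.0 + bin_size * np.arange(nbins[d] + 1)
        for d in range(3)
    )

    counts = np.zeros(tuple(nbins), dtype=np.int64)
    for frame in range(system.n_frames):
        hist, _ = np.histogramdd(positions[frame][selection], bins=edges)
        counts += hist.astype(np.int64)
    grid = DensityGrid(
        counts=counts,
        edges=edges,
        bin_size=bin_size,
        center=center,
        samples=int(counts.sum()),
    )
    logger.info(
        "accumulated %d bead-frames on a %s voxel grid", grid.samples, counts.shape
    )
    return grid


def site_mask(
    grid: DensityGrid, site_center: np.ndarray, radius: float
) -> RegionMask:
    """Spherical site mask: voxels whose centres lie within ``radius`` (nm)."""
    if radius <= grid.bin_size:
        raise ValueError("site radius must exceed the bin size")
    cx, cy, cz = grid.voxel_centers()
    site_center = np.asarray(site_center, dtype=float)
    d2 = (
        (cx[:, None, None] - site_center[0]) ** 2
        + (cy[None, :, None] - site_center[1]) ** 2
        + (cz[None, None, :] - site_center[2]) ** 2
    )
    mask = d2 <= radius**2
    if not mask.any():
        raise ValueError("site mask is empty; is the site inside the grid?")
    return RegionMask(mask=mask, kind="site")


def bulk_mask(
    grid: DensityGrid,
    protein_positions: np.ndarray | None,
    z_slab: tuple[float, float],
    min_protein_distance: float = 2.0,
    exclude: Sequence[RegionMask] = (),
) -> RegionMask:
    """Bulk-membrane mask: in-slab voxels far from the protein.

    Voxels whose centres lie within the z slab (nm bounds), farther than
    ``min_protein_distance`` from every protein bead (reference-frame
    positions), and outside all ``exclude`` masks (e.g. site masks).
    """
    cx, cy, cz = grid.voxel_centers()
    mask = np.ones(grid.counts.shape, dtype=bool)
    z_ok = (cz >= z_slab[0]) & (cz <= z_slab[1])
    mask &= z_ok[None, None, :]
    if protein_positions is not None and len(protein_positions):
        protein_positions = np.asarray(protein_positions, dtype=float)
        centers = np.stack(
            np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(protein_positions).query(centers)
        mask &= (dist > min_protein_distance).reshape(grid.counts.shape)
    for region in exclude:
        mask &= ~region.mask
    if not mask.any():
        raise ValueError("bulk mask is empty; relax the slab/distance settings")
    return RegionMask(mask=mask, kind="bulk")


def binding_free_energy(
    grid: DensityGrid,
    site: RegionMask,
    bulk: RegionMask,
    temperature: float,
    gas_constant: float = GAS_CONSTANT_KJ,
) -> float:
    """dG = -RT ln(mean site density / mean bulk density), in kJ/mol.

    Zero bulk density is an error; zero site density returns +inf with a
    warning (the site was never visited).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if np.any(site.mask & bulk.mask):
        raise ValueError("site and bulk masks must be disjoint")
    density = grid.density
    rho_site = float(density[site.mask].mean())
    rho_bulk = float(density[bulk.mask].mean())
    if rho_bulk <= 0:
        raise ValueError("bulk mask has zero mean density")
    if rho_site <= 0:
        warnings.warn("site mask has zero density; returning +inf", stacklevel=2)
        return math.inf
    return -gas_constant * temperature * math.log(rho_site / rho_bulk)
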