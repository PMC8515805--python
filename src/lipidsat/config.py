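"""Run configuration schema: structured YAML with strict validation.

Unknown keys are rejected so that a misspelt cutoff cannot silently fall
back to a default. All numeric parameters used by a run are echoed into the
run log, so reports never depend on silent defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ContactCutoffs(_StrictModel):
    lower: float = 0.55
    upper: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "ContactCutoffs":
        if not 0 < self.lower <= self.upper:
            raise ValueError("need 0 < lower <= upper contact cutoff")
        return self


class SiteSpec(_StrictModel):
    site_id: str
    residues: list[tuple[str, int]]


class SyntheticSiteSpec(_StrictModel):
    """Kinetic ground-truth model for one synthetic site."""

    site_id: str
    kd: float = Field(gt=0, description="ground-truth Kd in percent")
    k_off: float = Field(default=0.1, gt=0, description="per-frame off rate")
    emission: float = Field(default=1.0, gt=0, le=1)
    n_residues: int = Field(default=6, ge=1)


class SyntheticSpec(_StrictModel):
    sites: list[SyntheticSiteSpec]
    concentrations: list[float] = [1.0, 2.5, 5.0, 10.0, 15.0, 30.0, 40.0]
    replicates: int = Field(default=3, ge=1)
    frames: int = Field(default=20_000, ge=1)


class ManifestEntry(_StrictModel):
    coordinates: str
    trajectory: Optional[str] = None
    cholesterol_percent: float = Field(ge=0, le=100)
    replicate: int = 0

    def check_files(self) -> None:
        if not Path(self.coordinates).exists():
            raise FileNotFoundError(self.coordinates)
        if self.trajectory is not None and not Path(self.trajectory).exists():
            raise FileNotFoundError(self.trajectory)


class GridSpec(_StrictModel):
    extents: tuple[float, float, float] = (10.0, 10.0, 10.0)
    bin_size: float = Field(default=0.1, gt=0)
    align: bool = True


class DensitySiteSpec(_StrictModel):
    site_id: str
    center: tuple[float, float, float]
    radius: float = Field(gt=0)


class DensitySpec(_StrictModel):
    sites: list[DensitySiteSpec]
    z_slab: Optional[tuple[float, float]] = None
    min_protein_distance: float = Field(default=2.0, ge=0)
    bead_selection: Literal["all", "head"] = "all"


class SpatialSpec(_StrictModel):
    """Synthetic spatial-ensemble input for density/exposure runs."""

    box: tuple[float, float, float] = (12.0, 12.0, 9.0)
    protein_radius: float = Field(default=1.2, gt=0)
    membrane_half_thickness: float = Field(default=2.0, gt=0)
    sites: list[DensitySiteSpec] = []
    well_depths: list[float] = []
    n_chol_per_leaflet: int = Field(default=50, ge=1)
    n_popc_per_leaflet: int = Field(default=100, ge=1)
    frames: int = Field(default=100, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "SpatialSpec":
        if len(self.well_depths) != len(self.sites):
            raise ValueError("one well depth per spatial site is required")
        return self


class RunConfig(_StrictModel):
    """Top-level run configuration (see README for a worked example)."""

    temperature: float = Field(default=310.0, gt=0)
    seed: int = 0
    contact_cutoffs: ContactCutoffs = ContactCutoffs()
    free_ligand_exclusion: float = Field(default=0.8, gt=0)
    exposure_cutoff: float = Field(default=0.6, gt=0)
    stride: int = Field(default=1, ge=1)
    species_map: Optional[dict[str, str]] = None
    sites: list[SiteSpec] = []
    synthetic: Optional[SyntheticSpec] = None
    spatial: Optional[SpatialSpec] = None
    manifest: list[ManifestEntry] = []
    grid: GridSpec = GridSpec()
    density: Optional[DensitySpec] = None
    output_dir: str = "lipidsat_out"

    def validate_for_saturation(self) -> None:
        if self.synthetic is not None:
            if len(self.synthetic.concentrations) < 3:
                raise ValueError("saturation runs need >= 3 concentrations")
            if not self.synthetic.sites:
                raise ValueError("synthetic saturation runs need >= 1 site")
            return
        if not self.manifest:
            raise ValueError("either a synthetic spec or a manifest is required")
        conditions = {e.cholesterol_percent for e in self.manifest}
        if len(conditions) < 3:
            raise ValueError(
                f"saturation runs need >= 3 distinct conditions, got {len(conditions)}"
            )
        if not self.sites:
            raise ValueError("manifest-based runs need site definitions")
        if self.species_map is None:
            raise ValueError("manifest-based runs need a species_map")
        for entry in self.manifest:
            entry.check_files()


def load_config(path: str | Path) -> RunConfig:
    """Parse and strictly validate a YAML run configuration."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    return RunConfig.model_validate(raw)
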