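"""Simulation configuration.

All physical lengths are in nanometres; intensities are in detected photons
(camera gain is fixed at 1, so photons map 1:1 to grey levels). Coordinates
are 0-based ``(z, y, x)`` voxel indices and object positions may be
fractional.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator

#: Genome sizes (kb) of the three bacteriophage calibration standards.
PHAGE_GENOME_KB: dict[str, float] = {"lambda": 48.0, "P1": 90.0, "T4": 168.0}

PHAGE_CLASSES = ("lambda", "P1", "T4")


class ChromatinMass(BaseModel):
    """Optional bright chromatin blob the kinetochores stretch away from."""

    position: Optional[tuple[float, float, float]] = None  # (z, y, x); auto-placed if None
    total_kb: float = Field(2000.0, gt=0)
    sigma_nm: tuple[float, float] = (450.0, 700.0)  # (z, xy)


class SimConfig(BaseModel):
    """Parameters of one simulated two-channel acquisition field.

    Defaults emulate the acquisition conditions of the quantification
    protocol this package implements: 1,024 x 1,024 px planes in z-stacks
    with a 200 nm step, a 100x/1.4 NA objective sampled at 65 nm/px, and
    as-if-deconvolved images (compact Gaussian PSF, no out-of-focus haze
    beyond a flat background level).
    """

    field_shape: tuple[int, int, int] = (21, 1024, 1024)  # (z, y, x)
    voxel_size_nm: tuple[float, float] = (200.0, 65.0)  # (z, xy)
    psf_sigma_nm: tuple[float, float] = (300.0, 100.0)  # (z, xy) for point sources
    # As-if-deconvolved point sources are axially confined to their focal
    # plane: phages get this sub-step axial sigma and sit at plane centres.
    phage_axial_sigma_nm: float = 30.0
    snap_phage_to_plane: bool = True

    brightness_per_kb: float = Field(200.0, gt=0)  # expected DAPI photons per kb
    gfp_brightness: float = Field(15000.0, ge=0)  # photons per kinetochore
    background_dapi: float = Field(5.0, ge=0)  # photons/voxel
    background_gfp: float = Field(2.0, ge=0)
    read_noise_sd: float = Field(2.0, ge=0)  # photons
    poisson_noise: bool = True

    n_phage_per_class: int = Field(3, ge=0)
    n_kinetochores: int = Field(5, ge=0)
    kinetochore_kb_range: tuple[float, float] = (28.0, 147.0)
    kinetochore_kb_values: Optional[list[float]] = None  # overrides the uniform draw
    kinetochore_sigma_nm: tuple[float, float] = (300.0, 250.0)  # (z, xy) blob extent
    chromatin_mass: Optional[ChromatinMass] = None
    marker_labels: list[str] = ["CENP-A"]  # cycled over kinetochores

    # Per-class multiplier on expected DAPI photons per kb; models the dye's
    # AT-composition preference. 1.0 (no bias) unless overridden.
    at_bias_factor: dict[str, float] = {}

    camera_bit_depth: int = Field(16, ge=8, le=16)
    placement_margin_px: float = Field(30.0, ge=0)  # extra pairwise clearance
    placement_retries: int = 500
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if any(s <= 0 for s in self.field_shape):
            raise ValueError("field_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel sizes must be positive")
        if any(s <= 0 for s in self.psf_sigma_nm) or self.phage_axial_sigma_nm <= 0:
            raise ValueError("PSF sigmas must be positive")
        if any(s <= 0 for s in self.kinetochore_sigma_nm):
            raise ValueError("kinetochore blob sigmas must be positive")
        lo, hi = self.kinetochore_kb_range
        if not (0 < lo <= hi):
            raise ValueError("kinetochore_kb_range must satisfy 0 < min <= max")
        if self.kinetochore_kb_values is not None:
            if len(self.kinetochore_kb_values) != self.n_kinetochores:
                raise ValueError("kinetochore_kb_values length must equal n_kinetochores")
            if any(kb <= 0 for kb in self.kinetochore_kb_values):
                raise ValueError("kinetochore kb values must be positive")
        if any(f <= 0 for f in self.at_bias_factor.values()):
            raise ValueError("at_bias_factor entries must be positive")
        if not self.marker_labels:
            raise ValueError("marker_labels must be non-empty")
        return self

    # -- derived geometry (voxel units) ------------------------------------

    def sigma_vox(self, sigma_nm: tuple[float, float]) -> tuple[float, float, float]:
        """Convert an (z, xy) nm sigma pair to (z, y, x) voxel units."""
        vz, vxy = self.voxel_size_nm
        return (sigma_nm[0] / vz, sigma_nm[1] / vxy, sigma_nm[1] / vxy)

    def bias(self, object_class: str) -> float:
        return self.at_bias_factor.get(object_class, 1.0)

    @property
    def max_grey(self) -> float:
        return float(2 ** self.camera_bit_depth - 1)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
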