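"""Multi-channel 3-D image fields, TIFF I/O and z-projections.

Quantification downstream consumes either a single in-focus plane (phage
standards) or a sum projection over a z-range (kinetochores); maximum
projections are for display/QC only and are rejected by the measurement
operations via the plane's ``kind`` tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import tifffile

from .errors import FormatError

PlaneKind = Literal["single-plane", "sum-projection", "max-projection"]

#: Plane kinds that intensity measurements may consume.
QUANTIFIABLE_KINDS = ("single-plane", "sum-projection")


@dataclass
class ImageField:
    """A registered multi-channel 3-D intensity stack with voxel geometry."""

    channels: dict[str, np.ndarray]  # name -> (z, y, x) array
    voxel_size_nm: tuple[float, float] = (200.0, 65.0)  # (z, xy)
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("field must have at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise FormatError(f"channel shapes differ: {shapes}")
        if any(arr.ndim != 3 for arr in self.channels.values()):
            raise FormatError("channels must be 3-D (z, y, x)")
        for name, arr in self.channels.items():
            if np.issubdtype(arr.dtype, np.floating):
                if not np.isfinite(arr).all():
                    raise FormatError(f"channel {name!r} has non-finite values")
            if float(arr.min()) < 0:
                raise FormatError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_planes(self) -> int:
        return self.shape[0]


@dataclass
class PlaneImage:
    """A 2-D image with provenance: a single plane or a z-projection."""

    pixels: np.ndarray
    kind: PlaneKind
    source: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise FormatError("PlaneImage pixels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_field(
    paths: Mapping[str, str | Path] | Sequence[str | Path],
    channel_names: Optional[Sequence[str]] = None,
    voxel_size_nm: tuple[float, float] = (200.0, 65.0),
) -> ImageField:
    """Read one multi-page TIFF stack per channel into an ImageField.

    ``paths`` is either a mapping {channel name: path} or a sequence of paths
    paired with ``channel_names``. Integer data are widened to float64 so
    downstream arithmetic is lossless.
    """
    if isinstance(paths, Mapping):
        items = list(paths.items())
    else:
        if channel_names is None or len(channel_names) != len(paths):
            raise FormatError("channel_names must match the number of paths")
        items = list(zip(channel_names, paths))
    channels: dict[str, np.ndarray] = {}
    for name, path in items:
        path = Path(path)
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # tifffile raises various types on bad input
            raise FormatError(f"not a readable TIFF: {path}") from exc
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise FormatError(f"{path}: expected a 2-D or 3-D stack, got {arr.shape}")
        channels[name] = np.asarray(arr, dtype=np.float64)
    return ImageField(channels=channels, voxel_size_nm=voxel_size_nm,
                      metadata={"source_files": {n: str(p) for n, p in items}})


def write_field(field: ImageField, out_dir: str | Path) -> dict[str, Path]:
    """Write each channel as a multi-page TIFF; returns {channel: path}.

    Integer-valued data within 16-bit range are written as uint16 (lossless
    for camera counts); anything else is written as float32 TIFF pages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, arr in field.channels.items():
        path = out / f"{name}.tif"
        if np.issubdtype(arr.dtype, np.integer):
            data = arr
        elif np.all(arr == np.round(arr)) and float(arr.max(initial=0)) <= 65535:
            data = arr.astype(np.uint16)
        else:
            data = arr.astype(np.float32)
        tifffile.imwrite(path, data, photometric="minisblack")
        paths[name] = path
    return paths


def _resolve_z_range(n_planes: int, z_range: Optional[tuple[int, int]]) -> tuple[int, int]:
    if z_range is None:
        return 0, n_planes
    lo, hi = z_range
    if not (0 <= lo < hi <= n_planes):
        raise ValueError(f"z_range {z_range} empty or outside stack of {n_planes} planes")
    return lo, hi


def sum_project(
    field: ImageField, channel: str, z_range: Optional[tuple[int, int]] = None
) -> PlaneImage:
    """Pixel-wise sum over a half-open z-range; conserves total intensity."""
    lo, hi = _resolve_z_range(field.n_planes, z_range)
    pixels = field.channels[channel][lo:hi].sum(axis=0)
    return PlaneImage(pixels=pixels, kind="sum-projection",
                      source=f"{channel}[z={lo}:{hi}]")


def max_project(
    field: ImageField, channel: str, z_range: Optional[tuple[int, int]] = None
) -> PlaneImage:
    """Pixel-wise maximum over a z-range. Display/QC only, never quantified."""
    lo, hi = _resolve_z_range(field.n_planes, z_range)
    pixels = field.channels[channel][lo:hi].max(axis=0)
    return PlaneImage(pixels=pixels, kind="max-projection",
                      source=f"{channel}[z={lo}:{hi}]")


def single_plane(field: ImageField, channel: str, z: int) -> PlaneImage:
    """Extract one plane as a quantifiable PlaneImage."""
    if not (0 <= z < field.n_planes):
        raise ValueError(f"plane {z} outside stack of {field.n_planes}")
    return PlaneImage(pixels=field.channels[channel][z], kind="single-plane",
                      source=f"{channel}[z={z}]")
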