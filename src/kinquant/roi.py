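"""ROI sum-intensity measurement with shifted-ROI background subtraction.

This module codifies the manual measurement protocol: sum the pixel values
under a region of interest, move a copy of the same ROI a few pixels away
onto empty background, sum it there, and report net = sum - background.

The background copy is translated so its bounding box clears the original
by ``shift_px`` pixels (the protocol's 5-10 px move, measured as edge
clearance so the background region never overlaps the object being
measured). Eight compass directions are tried; the candidate overlapping
the fewest forbidden (foreground) pixels wins, with ties broken by lowest
sum and then by the fixed direction order N, NE, E, SE, S, SW, W, NW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import NoBackgroundPositionError, RoiError
from .image import PlaneImage, QUANTIFIABLE_KINDS

#: Fixed candidate order for background placement (dy, dx unit steps).
COMPASS = (
    ("N", (-1, 0)), ("NE", (-1, 1)), ("E", (0, 1)), ("SE", (1, 1)),
    ("S", (1, 0)), ("SW", (1, -1)), ("W", (0, -1)), ("NW", (-1, -1)),
)


@dataclass(frozen=True)
class Roi:
    """A non-empty 2-D pixel mask, stored at full plane size."""

    mask: np.ndarray  # bool, shape = plane shape

    def __post_init__(self) -> None:
        m = self.mask
        if m.ndim != 2 or m.dtype != bool:
            raise RoiError("Roi mask must be a 2-D boolean array")
        if not m.any():
            raise RoiError("Roi is empty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(y0, x0, y1, x1), half-open."""
        ys, xs = np.nonzero(self.mask)
        return int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1

    @property
    def origin(self) -> tuple[int, int]:
        y0, x0, _, _ = self.bbox
        return y0, x0

    @property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())

    def translated(self, dy: int, dx: int) -> Optional["Roi"]:
        """Translate the mask; None if any pixel would leave the plane."""
        ys, xs = np.nonzero(self.mask)
        ny, nx = self.mask.shape
        ys2, xs2 = ys + dy, xs + dx
        if ys2.min() < 0 or xs2.min() < 0 or ys2.max() >= ny or xs2.max() >= nx:
            return None
        out = np.zeros_like(self.mask)
        out[ys2, xs2] = True
        return Roi(out)

    def dilated(self, radius: int) -> "Roi":
        if radius <= 0:
            return self
        return Roi(ndimage.binary_dilation(self.mask, structure=disk(radius)))

    def overlap(self, other_mask: np.ndarray) -> int:
        return int(np.count_nonzero(self.mask & other_mask))

    # -- run-length encoding (flat, row-major) -----------------------------

    def to_rle(self) -> str:
        """Serialize as 'H,W;start:length ...' over the flattened mask."""
        flat = self.mask.ravel()
        edges = np.flatnonzero(np.diff(np.concatenate(([0], flat.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        runs = " ".join(f"{s}:{e - s}" for s, e in zip(starts, ends))
        h, w = self.mask.shape
        return f"{h},{w};{runs}"

    @classmethod
    def from_rle(cls, text: str) -> "Roi":
        header, runs = text.split(";")
        h, w = (int(v) for v in header.split(","))
        flat = np.zeros(h * w, dtype=bool)
        for run in runs.split():
            start, length = (int(v) for v in run.split(":"))
            flat[start:start + length] = True
        return cls(flat.reshape(h, w))

    @classmethod
    def from_bbox(cls, plane_shape: tuple[int, int], y0: int, x0: int,
                  y1: int, x1: int) -> "Roi":
        mask = np.zeros(plane_shape, dtype=bool)
        mask[y0:y1, x0:x1] = True
        return cls(mask)


@dataclass
class IntensityMeasurement:
    """sum / background / net triple for one ROI, with provenance flags."""

    sum_value: float
    background_value: float
    shift_used: tuple[int, int]  # (dy, dx) actually applied
    flags: frozenset[str] = frozenset()

    @property
    def net(self) -> float:
        return self.sum_value - self.background_value


def _check_plane_roi(plane: PlaneImage, roi: Roi) -> None:
    if plane.kind not in QUANTIFIABLE_KINDS:
        raise RoiError(f"cannot quantify on a {plane.kind!r} image")
    if plane.shape != roi.mask.shape:
        raise RoiError(f"ROI shape {roi.mask.shape} != plane shape {plane.shape}")


def sum_intensity(plane: PlaneImage, roi: Roi) -> float:
    """Sum of pixel intensities under the ROI mask."""
    _check_plane_roi(plane, roi)
    return float(plane.pixels[roi.mask].sum())


def background_candidates(roi: Roi, shift_px: int) -> list[tuple[str, tuple[int, int], Roi]]:
    """The 8 translated background ROIs that stay fully inside the plane.

    Translation along an axis is the ROI's bbox extent on that axis plus
    ``shift_px``, guaranteeing an edge clearance of ``shift_px`` pixels.
    """
    if not (5 <= shift_px <= 10):
        raise ValueError("shift_px must be between 5 and 10 pixels")
    y0, x0, y1, x1 = roi.bbox
    h, w = y1 - y0, x1 - x0
    out = []
    for name, (uy, ux) in COMPASS:
        cand = roi.translated(uy * (h + shift_px), ux * (w + shift_px))
        if cand is not None:
            out.append((name, (uy * (h + shift_px), ux * (w + shift_px)), cand))
    return out


def background_intensity(
    plane: PlaneImage,
    roi: Roi,
    shift_px: int = 8,
    forbidden: Optional[Sequence[np.ndarray]] = None,
) -> tuple[float, tuple[int, int], frozenset[str]]:
    """Background sum from the best shifted copy of the same ROI.

    Returns (background sum, (dy, dx) shift used, flags). Flags contain
    ``background-overlap`` when even the best candidate intersects a
    forbidden foreground mask.
    """
    _check_plane_roi(plane, roi)
    candidates = background_candidates(roi, shift_px)
    if not candidates:
        raise NoBackgroundPositionError("no valid background position")
    if forbidden:
        union = np.zeros(plane.shape, dtype=bool)
        for m in forbidden:
            union |= m
    else:
        union = None
    best = None
    for _, shift, cand in candidates:
        ov = cand.overlap(union) if union is not None else 0
        s = float(plane.pixels[cand.mask].sum())
        key = (ov, s)
        if best is None or key < best[0]:
            best = (key, shift, ov, s)
    _, shift, overlap, bg = best
    flags = frozenset({"background-overlap"}) if overlap > 0 else frozenset()
    return bg, shift, flags


def net_intensity(
    plane: PlaneImage,
    roi: Roi,
    shift_px: int = 8,
    forbidden: Optional[Sequence[np.ndarray]] = None,
) -> IntensityMeasurement:
    """net = sum - background for one ROI; negative nets flagged, not clamped."""
    s = sum_intensity(plane, roi)
    bg, shift, flags = background_intensity(plane, roi, shift_px, forbidden)
    if s - bg < 0:
        flags = flags | {"negative-net"}
    return IntensityMeasurement(sum_value=s, background_value=bg,
                                shift_used=shift, flags=frozenset(flags))


def line_profile(
    planes: dict[str, PlaneImage],
    p0: tuple[float, float],
    p1: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Bilinear intensity series along the segment p0 -> p1, one per channel.

    Samples at unit-pixel spacing; series length is ceil(|p1 - p0|) + 1.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    n = int(np.ceil(np.linalg.norm(p1 - p0))) + 1
    ts = np.linspace(0.0, 1.0, n)
    coords = np.outer(1 - ts, p0) + np.outer(ts, p1)  # (n, 2) as (y, x)
    out = {}
    for name, plane in planes.items():
        ny, nx = plane.shape
        for p in (p0, p1):
            if not (0 <= p[0] <= ny - 1 and 0 <= p[1] <= nx - 1):
                raise RoiError(f"profile endpoint {tuple(p)} outside plane")
        out[name] = ndimage.map_coordinates(
            np.asarray(plane.pixels, dtype=float), coords.T, order=1, mode="nearest")
    return out
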