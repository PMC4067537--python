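"""Detect phage particles, measure them, and assign lambda/P1/T4 classes.

The calibration standards are bacteriophage particles of known genome size
(lambda 48 kb, P1 90 kb, T4 168 kb) imaged in the same field as the
specimens. Each particle is measured on its best single in-focus plane
with the shifted-ROI background protocol; class assignment is 1-D k-means
on net intensity with a genome-ratio QC gate (cluster means must scale as
48:90:168 within +/-25% pairwise, or the offending clusters are marked
unassigned).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure as sk_measure

from .config import PHAGE_CLASSES, PHAGE_GENOME_KB
from .errors import IncompleteStandardSetError
from .image import ImageField, PlaneImage, single_plane
from .roi import IntensityMeasurement, Roi, net_intensity


@dataclass
class DetectionParams:
    """Thresholding/segmentation knobs for automated spot detection."""

    k_mad: float = 5.0          # threshold = median + k_mad * MAD
    min_area: int = 4           # px, inclusive
    max_area: int = 400         # px, inclusive
    dilate_px: int = 2          # ROI = component dilated by this much
    # When MAD == 0 (noiseless synthetic planes) fall back to this fraction
    # of (max - median) above the median.
    degenerate_frac: float = 0.01


@dataclass
class SpotRecord:
    """One detected spot: where it is, what it measured, what it was called."""

    spot_id: str
    centroid: tuple[float, float, float]  # (z, y, x)
    plane_index: int
    roi: Roi
    measurement: IntensityMeasurement
    assigned_class: str = "unassigned"
    qc_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class StandardPoint:
    """(genome kb, net intensity) pair contributed by one measured spot."""

    genome_kb: float
    net_intensity: float
    spot_id: str = ""


def detection_threshold(pixels: np.ndarray, params: DetectionParams) -> float:
    med = float(np.median(pixels))
    mad = float(np.median(np.abs(pixels - med)))
    if mad > 0:
        return med + params.k_mad * mad
    return med + params.degenerate_frac * (float(pixels.max()) - med)


def detect_spots(
    plane: PlaneImage,
    params: Optional[DetectionParams] = None,
    qc_notes: Optional[list[str]] = None,
) -> list[Roi]:
    """Threshold + connected components; returns disjoint ROIs sorted by (y, x).

    Components touching the image border are dropped (noted in ``qc_notes``
    when given); surviving components are dilated by ``dilate_px`` and any
    pixels contested between two dilated ROIs go to the first in sort order.
    """
    params = params or DetectionParams()
    px = np.asarray(plane.pixels, dtype=float)
    if px.min() < 0:
        raise ValueError("detection requires a non-negative plane")
    thr = detection_threshold(px, params)
    fg = px > thr
    labels = sk_measure.label(fg, connectivity=2)
    ny, nx = px.shape
    comps = []
    for region in sk_measure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        if y0 == 0 or x0 == 0 or y1 == ny or x1 == nx:
            if qc_notes is not None:
                qc_notes.append(f"dropped border component at {region.centroid}")
            continue
        if not (params.min_area <= region.area <= params.max_area):
            continue
        comps.append((region.centroid, labels == region.label))
    comps.sort(key=lambda c: (c[0][0], c[0][1]))
    rois: list[Roi] = []
    taken = np.zeros_like(fg)
    for _, mask in comps:
        roi = Roi(mask).dilated(params.dilate_px)
        free = roi.mask & ~taken
        if not free.any():
            continue
        roi = Roi(free)
        taken |= roi.mask
        rois.append(roi)
    return rois


def select_focus_plane(
    field: ImageField, channel: str, candidate_region: np.ndarray | Roi
) -> int:
    """Plane index maximizing total in-region intensity (ties -> lower index)."""
    mask = candidate_region.mask if isinstance(candidate_region, Roi) else candidate_region
    if not mask.any():
        raise ValueError("candidate region is empty")
    stack = field.channels[channel]
    sums = stack[:, mask].sum(axis=1)
    return int(np.argmax(sums))


def measure_spot(
    field: ImageField,
    channel: str,
    roi: Roi,
    spot_id: str,
    shift_px: int = 8,
    forbidden: Optional[Sequence[np.ndarray]] = None,
) -> SpotRecord:
    """Measure one spot on its best single plane with background subtraction."""
    z = select_focus_plane(field, channel, roi)
    plane = single_plane(field, channel, z)
    meas = net_intensity(plane, roi, shift_px=shift_px, forbidden=forbidden)
    cy, cx = roi.centroid
    return SpotRecord(spot_id=spot_id, centroid=(float(z), cy, cx),
                      plane_index=z, roi=roi, measurement=meas,
                      qc_flags=meas.flags)


def _kmeans_1d(values: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D 3-means: centers seeded at the 1/6, 3/6, 5/6 quantiles."""
    centers = np.quantile(values, [1 / 6, 3 / 6, 5 / 6])
    assign = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centers[None, :])
        new_assign = np.argmin(d, axis=1)
        for k in range(3):
            if not np.any(new_assign == k):
                raise IncompleteStandardSetError(
                    "incomplete standard set: empty intensity cluster")
            centers[k] = values[new_assign == k].mean()
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    order = np.argsort(centers)
    remap = np.empty(3, dtype=int)
    remap[order] = np.arange(3)
    return remap[assign], centers[order]


#: Pairwise tolerance on cluster-mean ratios vs the genome-size ratios.
RATIO_TOLERANCE = 0.25


def assign_classes(spots: Sequence[SpotRecord]) -> list[SpotRecord]:
    """Cluster spots by net intensity into lambda < P1 < T4.

    Requires >= 3 spots with positive net intensity. Clusters whose mean
    ratios do not match the genome-size ratios 48:90:168 within +/-25% are
    flagged unassigned; an empty cluster raises because a usable standard
    field must contain all three phages.
    """
    usable = [s for s in spots if s.measurement.net > 0]
    if len(usable) < 3:
        raise IncompleteStandardSetError(
            "incomplete standard set: need >= 3 spots with positive net intensity")
    nets = np.array([s.measurement.net for s in usable])
    assign, centers = _kmeans_1d(nets)
    kbs = [PHAGE_GENOME_KB[c] for c in PHAGE_CLASSES]
    bad = set()
    for k in range(2):
        expected = kbs[k + 1] / kbs[k]
        observed = centers[k + 1] / centers[k]
        if not (1 - RATIO_TOLERANCE <= observed / expected <= 1 + RATIO_TOLERANCE):
            bad.update({k, k + 1})
    out = []
    by_id = {id(s): None for s in spots}
    for s, k in zip(usable, assign):
        if k in bad:
            label, flags = "unassigned", s.qc_flags | {"ratio-qc-failed"}
        else:
            label, flags = PHAGE_CLASSES[k], s.qc_flags
        by_id[id(s)] = (label, flags)
    for s in spots:
        if by_id[id(s)] is None:  # non-positive net: never assignable
            out.append(SpotRecord(**{**s.__dict__, "assigned_class": "unassigned",
                                     "qc_flags": s.qc_flags | {"non-positive-net"}}))
        else:
            label, flags = by_id[id(s)]
            out.append(SpotRecord(**{**s.__dict__, "assigned_class": label,
                                     "qc_flags": frozenset(flags)}))
    return out


def assign_classes_from_manifest(
    spots: Sequence[SpotRecord],
    manifest_phages: pd.DataFrame,
    max_dist_px: float = 4.0,
) -> list[SpotRecord]:
    """Known-identity assignment by nearest manifest position (oracle mode)."""
    out = []
    pos = manifest_phages[["y", "x"]].to_numpy(dtype=float)
    classes = manifest_phages["class"].to_numpy()
    for s in spots:
        _, cy, cx = s.centroid
        d = np.hypot(pos[:, 0] - cy, pos[:, 1] - cx)
        j = int(np.argmin(d))
        if d[j] <= max_dist_px:
            label, flags = str(classes[j]), s.qc_flags
        else:
            label, flags = "unassigned", s.qc_flags | {"no-manifest-match"}
        out.append(SpotRecord(**{**s.__dict__, "assigned_class": label,
                                 "qc_flags": frozenset(flags)}))
    return out


def make_standard_points(spots: Sequence[SpotRecord]) -> list[StandardPoint]:
    """Assigned spots -> (genome kb, net intensity) standard points."""
    points = []
    for s in spots:
        if s.assigned_class in PHAGE_GENOME_KB:
            points.append(StandardPoint(genome_kb=PHAGE_GENOME_KB[s.assigned_class],
                                        net_intensity=s.measurement.net,
                                        spot_id=s.spot_id))
    return points


def spots_table(spots: Sequence[SpotRecord]) -> pd.DataFrame:
    """Flat per-spot table (spot_id, z, y, x, sum, background, net, class, flags)."""
    rows = []
    for s in spots:
        z, y, x = s.centroid
        rows.append(dict(spot_id=s.spot_id, z=z, y=y, x=x,
                         sum=s.measurement.sum_value,
                         background=s.measurement.background_value,
                         net=s.measurement.net,
                         assigned_class=s.assigned_class,
                         flags=";".join(sorted(s.qc_flags))))
    return pd.DataFrame(rows, columns=["spot_id", "z", "y", "x", "sum",
                                       "background", "net", "assigned_class", "flags"])
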