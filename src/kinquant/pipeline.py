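"""End-to-end analysis of one acquisition field.

Ties the stages together: detect phage standards in the DAPI channel,
measure them on single in-focus planes, fit the per-session standard
curve, then segment each GFP kinetochore envelope and convert its net
DAPI sum to kilobases. Matching helpers compare results against a
simulation's ground-truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationFit, fit_standard_curve
from .image import ImageField, sum_project
from .kinetochore import (EnvelopeParams, KinetochoreRecord, measure_kinetochore,
                          segment_envelope)
from .roi import Roi
from .simulate import GroundTruthManifest
from .standards import (DetectionParams, SpotRecord, StandardPoint,
                        assign_classes, assign_classes_from_manifest,
                        detect_spots, detection_threshold, make_standard_points,
                        measure_spot)


@dataclass
class FieldAnalysis:
    """Everything measured on one field."""

    spots: list[SpotRecord]
    standard_points: list[StandardPoint]
    fit: CalibrationFit
    records: list[KinetochoreRecord]
    session: str = ""


def _default_gfp_params() -> DetectionParams:
    # Kinetochore GFP blobs are larger than phage spots; loosen the area gate.
    return DetectionParams(min_area=9, max_area=5000, dilate_px=2)


def analyze_field(
    field: ImageField,
    session: str = "session-1",
    manifest: Optional[GroundTruthManifest] = None,
    shift_px: int = 8,
    dapi_params: Optional[DetectionParams] = None,
    gfp_params: Optional[DetectionParams] = None,
    envelope_params: Optional[EnvelopeParams] = None,
    dapi_channel: str = "DAPI",
    gfp_channel: str = "GFP",
) -> FieldAnalysis:
    """Run the full quantification on one field.

    When a ground-truth ``manifest`` is supplied it provides kinetochore
    seed points and known-identity phage assignment (oracle mode);
    otherwise seeds come from GFP spot detection and phage classes from
    intensity clustering.
    """
    dapi_params = dapi_params or DetectionParams()
    gfp_params = gfp_params or _default_gfp_params()

    dapi_proj = sum_project(field, dapi_channel)
    gfp_proj = sum_project(field, gfp_channel)

    # Foreground masks: everything above threshold in either channel is
    # off-limits for background ROIs.
    dapi_fg = dapi_proj.pixels > detection_threshold(dapi_proj.pixels, dapi_params)
    gfp_fg = gfp_proj.pixels > detection_threshold(gfp_proj.pixels, gfp_params)
    forbidden = [dapi_fg | gfp_fg]

    # Kinetochore seeds.
    if manifest is not None:
        seeds = [(row.y, row.x) for row in manifest.kinetochores.itertuples()]
        markers = [row.marker for row in manifest.kinetochores.itertuples()]
    else:
        gfp_rois = detect_spots(gfp_proj, gfp_params)
        seeds = [r.centroid for r in gfp_rois]
        markers = ["" for _ in seeds]

    # Phage candidates: DAPI spots that carry no GFP.
    spots_rois = detect_spots(dapi_proj, dapi_params)
    phage_rois = [r for r in spots_rois
                  if not gfp_fg[int(round(r.centroid[0])), int(round(r.centroid[1]))]]

    spots = [measure_spot(field, dapi_channel, roi, spot_id=f"{session}-spot{i:03d}",
                          shift_px=shift_px, forbidden=forbidden)
             for i, roi in enumerate(phage_rois)]
    if manifest is not None:
        spots = assign_classes_from_manifest(spots, manifest.phages)
    else:
        spots = assign_classes(spots)
    points = make_standard_points(spots)
    fit = fit_standard_curve(points, session=session)

    records = []
    for i, (seed, marker) in enumerate(zip(seeds, markers)):
        envelope, z_range, env_flags = segment_envelope(
            field, seed, gfp_channel=gfp_channel, params=envelope_params)
        records.append(measure_kinetochore(
            field, envelope, z_range, fit, shift_px=shift_px, forbidden=forbidden,
            dapi_channel=dapi_channel, record_id=f"{session}-k{i:03d}",
            marker=marker, session=session, envelope_flags=env_flags))
    return FieldAnalysis(spots=spots, standard_points=points, fit=fit,
                         records=records, session=session)


# -- ground-truth comparison helpers ---------------------------------------

def match_records_to_truth(
    records: Sequence[KinetochoreRecord], manifest: GroundTruthManifest
) -> pd.DataFrame:
    """Pair each record with its nearest manifest kinetochore.

    Returns a table with estimated vs true kb and the relative error.
    """
    kin = manifest.kinetochores
    pos = kin[["y", "x"]].to_numpy(dtype=float)
    rows = []
    for r in records:
        cy, cx = r.envelope.centroid
        d = np.hypot(pos[:, 0] - cy, pos[:, 1] - cx)
        j = int(np.argmin(d))
        true_kb = float(kin["true_kb"].iloc[j])
        rows.append(dict(record_id=r.record_id, marker=r.marker,
                         est_kb=r.estimate.kb, true_kb=true_kb,
                         match_dist_px=float(d[j]),
                         rel_error=(r.estimate.kb - true_kb) / true_kb,
                         flags=";".join(sorted(r.qc_flags))))
    return pd.DataFrame(rows)


def assignment_accuracy(
    spots: Sequence[SpotRecord], manifest: GroundTruthManifest,
    max_dist_px: float = 4.0,
) -> float:
    """Fraction of manifest-matched spots whose assigned class is correct."""
    phages = manifest.phages
    pos = phages[["y", "x"]].to_numpy(dtype=float)
    classes = phages["class"].to_numpy()
    matched = correct = 0
    for s in spots:
        _, cy, cx = s.centroid
        d = np.hypot(pos[:, 0] - cy, pos[:, 1] - cx)
        j = int(np.argmin(d))
        if d[j] <= max_dist_px:
            matched += 1
            if s.assigned_class == classes[j]:
                correct += 1
    if matched == 0:
        raise ValueError("no spots matched the manifest")
    return correct / matched
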