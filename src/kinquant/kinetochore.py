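"""GFP envelope segmentation and DAPI quantification of kinetochores.

Each stretched kinetochore is measured by (1) segmenting a 2-D envelope
from the GFP channel around a seed point — the half-max component of the
local GFP sum projection, grown to an aperture of ``aperture_nsigma``
Gaussian-equivalent sigmas so essentially all of the blob's flux falls
inside — (2) sum-projecting the DAPI channel over the planes where the
envelope carries GFP signal, (3) measuring net DAPI with the shifted-ROI
background protocol, and (4) converting to kilobases through the session's
phage standard curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure as sk_measure

from .calibration import CalibrationFit, DnaEstimate, predict_dna
from .errors import EmptyCohortError, NoGfpSignalError
from .image import ImageField, sum_project
from .roi import IntensityMeasurement, Roi, net_intensity

#: Half-max radius of a Gaussian in sigma units: sqrt(2 ln 2).
_HALF_MAX_NSIGMA = 1.1774


@dataclass
class EnvelopeParams:
    """Knobs for GFP envelope segmentation."""

    window_half_px: int = 15        # crop window = (2*half+1)^2 around the seed
    threshold_frac: float = 0.5     # of (local max - local background median)
    aperture_nsigma: float = 3.5    # grow the half-max component to this extent
    min_dilate_px: int = 1
    z_pad: int = 2                  # extra planes kept on both sides


@dataclass
class KinetochoreRecord:
    """One kinetochore's envelope, DAPI measurement and DNA estimate."""

    record_id: str
    envelope: Roi
    z_range: tuple[int, int]  # half-open planes projected
    measurement: IntensityMeasurement
    estimate: DnaEstimate
    marker: str = ""
    session: str = ""
    qc_flags: frozenset[str] = frozenset()


@dataclass
class CohortSummary:
    """Cohort statistics over includable kinetochore records."""

    n: int
    mean_kb: float
    sd_kb: Optional[float]  # None when n < 2
    min_kb: float
    max_kb: float
    per_marker: dict[str, "CohortSummary"] = dc_field(default_factory=dict)

    def to_text(self) -> str:
        sd = "NA" if self.sd_kb is None else f"{self.sd_kb:.1f}"
        lines = [f"n = {self.n}", f"mean_kb = {self.mean_kb:.1f}", f"sd_kb = {sd}",
                 f"min_kb = {self.min_kb:.1f}", f"max_kb = {self.max_kb:.1f}"]
        for marker, s in sorted(self.per_marker.items()):
            msd = "NA" if s.sd_kb is None else f"{s.sd_kb:.1f}"
            lines.append(f"{marker}: n = {s.n}, mean_kb = {s.mean_kb:.1f}, "
                         f"sd_kb = {msd}, range = ({s.min_kb:.1f}, {s.max_kb:.1f})")
        return "\n".join(lines)


def segment_envelope(
    field: ImageField,
    seed_point: tuple[float, float] | tuple[float, float, float],
    gfp_channel: str = "GFP",
    params: Optional[EnvelopeParams] = None,
) -> tuple[Roi, tuple[int, int], frozenset[str]]:
    """Segment one kinetochore's envelope from the GFP channel.

    ``seed_point`` is (y, x) or (z, y, x); only the lateral position is used.
    Returns (envelope ROI at full plane size, half-open z-range, flags).
    Raises when no GFP component exists at the seed.
    """
    params = params or EnvelopeParams()
    sy, sx = (seed_point[-2], seed_point[-1])
    stack = field.channels[gfp_channel]
    nz, ny, nx = stack.shape
    iy, ix = int(round(sy)), int(round(sx))
    if not (0 <= iy < ny and 0 <= ix < nx):
        raise ValueError("seed point outside field")
    h = params.window_half_px
    y0, y1 = max(0, iy - h), min(ny, iy + h + 1)
    x0, x1 = max(0, ix - h), min(nx, ix + h + 1)
    window = stack[:, y0:y1, x0:x1]
    wproj = window.sum(axis=0)

    bg_med = float(np.median(wproj))
    peak = float(wproj.max())
    if peak <= bg_med:
        raise NoGfpSignalError("no GFP signal: window is flat")
    thr = bg_med + params.threshold_frac * (peak - bg_med)
    labels = sk_measure.label(wproj >= thr, connectivity=2)
    seed_label = labels[iy - y0, ix - x0]
    if seed_label == 0:
        # Tolerate a seed a pixel or two off the blob's core.
        near = labels[max(0, iy - y0 - 2):iy - y0 + 3, max(0, ix - x0 - 2):ix - x0 + 3]
        cand = near[near > 0]
        if cand.size == 0:
            raise NoGfpSignalError("no GFP signal at seed point")
        seed_label = int(np.bincount(cand).argmax())
    comp = labels == seed_label

    flags: set[str] = set()
    ys, xs = np.nonzero(comp)
    if (ys.min() == 0 or xs.min() == 0
            or ys.max() == comp.shape[0] - 1 or xs.max() == comp.shape[1] - 1):
        flags.add("envelope-truncated")

    # Grow the half-max component to an aperture of aperture_nsigma Gaussian
    # sigmas, inferred from the component's equivalent radius.
    r_eq = float(np.sqrt(comp.sum() / np.pi))
    sigma_est = r_eq / _HALF_MAX_NSIGMA
    grow = max(params.min_dilate_px,
               int(np.ceil(params.aperture_nsigma * sigma_est - r_eq)))
    comp_roi = Roi(_embed(comp, (ny, nx), y0, x0)).dilated(grow)

    z_range = _gfp_z_range(window, comp, params.z_pad, nz_offset=0)
    return comp_roi, z_range, frozenset(flags)


def _embed(mask: np.ndarray, plane_shape: tuple[int, int], y0: int, x0: int) -> np.ndarray:
    out = np.zeros(plane_shape, dtype=bool)
    out[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]] = mask
    return out


def _gfp_z_range(window: np.ndarray, comp: np.ndarray, z_pad: int, nz_offset: int
                 ) -> tuple[int, int]:
    """Planes where the component's GFP exceeds its plane-wise background.

    Background per plane is estimated from window pixels outside the
    component (median x area, with a 2-sigma Poisson-ish guard scaled from
    the MAD); qualifying planes are padded by ``z_pad`` on both sides and at
    least one plane (the strongest) is always kept.
    """
    nz = window.shape[0]
    area = int(comp.sum())
    comp_sums = window[:, comp].sum(axis=1)
    outside = ~comp
    qualifying = []
    for z in range(nz):
        out_px = window[z][outside]
        med = float(np.median(out_px)) if out_px.size else 0.0
        mad = float(np.median(np.abs(out_px - med))) if out_px.size else 0.0
        sd_sum = 1.4826 * mad * np.sqrt(area)
        if comp_sums[z] > area * med + 2.0 * sd_sum:
            qualifying.append(z)
    if not qualifying:
        qualifying = [int(np.argmax(comp_sums))]
    lo = max(0, min(qualifying) - z_pad)
    hi = min(nz, max(qualifying) + 1 + z_pad)
    return lo + nz_offset, hi + nz_offset


def measure_kinetochore(
    field: ImageField,
    envelope: Roi,
    z_range: tuple[int, int],
    fit: CalibrationFit,
    shift_px: int = 8,
    forbidden: Optional[Sequence[np.ndarray]] = None,
    dapi_channel: str = "DAPI",
    record_id: str = "k0",
    marker: str = "",
    session: str = "",
    envelope_flags: frozenset[str] = frozenset(),
) -> KinetochoreRecord:
    """Net DAPI inside the envelope on a sum projection, converted to kb."""
    if session and fit.session and session != fit.session:
        raise ValueError(f"session mismatch: record {session!r} vs fit {fit.session!r}")
    proj = sum_project(field, dapi_channel, z_range)
    meas = net_intensity(proj, envelope, shift_px=shift_px, forbidden=forbidden)
    est = predict_dna(fit, meas.net)
    return KinetochoreRecord(
        record_id=record_id, envelope=envelope, z_range=z_range,
        measurement=meas, estimate=est, marker=marker, session=session,
        qc_flags=frozenset(envelope_flags | meas.flags | est.flags),
    )


def summarize_cohort(
    records: Sequence[KinetochoreRecord],
    include_flagged: bool = False,
) -> CohortSummary:
    """Mean, sample SD (n-1), min, max and n over includable records.

    By default records carrying QC flags (negative net, truncated envelope,
    background overlap, ...) are excluded from the headline numbers.
    """
    usable = [r for r in records if include_flagged or not r.qc_flags]
    if not usable:
        raise EmptyCohortError("no includable kinetochore records")
    summary = _stats([r.estimate.kb for r in usable])
    markers = sorted({r.marker for r in usable})
    if len(markers) > 1 or (markers and markers[0]):
        for marker in markers:
            kbs = [r.estimate.kb for r in usable if r.marker == marker]
            summary.per_marker[marker or "(unlabeled)"] = _stats(kbs)
    return summary


def _stats(kbs: Sequence[float]) -> CohortSummary:
    arr = np.asarray(kbs, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return CohortSummary(n=int(arr.size), mean_kb=float(arr.mean()), sd_kb=sd,
                         min_kb=float(arr.min()), max_kb=float(arr.max()))


def records_table(records: Sequence[KinetochoreRecord]) -> pd.DataFrame:
    """Flat per-record table; envelopes serialized as run-length encodings."""
    rows = []
    for r in records:
        rows.append(dict(
            record_id=r.record_id, session=r.session, marker=r.marker,
            z_lo=r.z_range[0], z_hi=r.z_range[1],
            sum=r.measurement.sum_value, background=r.measurement.background_value,
            net=r.measurement.net, kb=r.estimate.kb,
            ci_low=r.estimate.ci_low, ci_high=r.estimate.ci_high,
            flags=";".join(sorted(r.qc_flags)), envelope_rle=r.envelope.to_rle(),
        ))
    return pd.DataFrame(rows, columns=["record_id", "session", "marker", "z_lo",
                                       "z_hi", "sum", "background", "net", "kb",
                                       "ci_low", "ci_high", "flags", "envelope_rle"])
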