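"""Exception types raised by the quantification pipeline."""


class KinquantError(Exception):
    """Base class for all pipeline errors."""


class CrowdedFieldError(KinquantError):
    """Object placement failed after bounded retries: field too crowded."""


class SaturationRiskError(KinquantError):
    """An object's expected intensity would saturate >1% of its voxels."""


class FormatError(KinquantError):
    """Image files are malformed or inconsistent (shape/dtype/format)."""


class RoiError(KinquantError):
    """ROI is empty, outside the plane, or drawn on an unsupported plane kind."""


class NoBackgroundPositionError(KinquantError):
    """All shifted background candidates fall outside the plane."""


class IncompleteStandardSetError(KinquantError):
    """Fewer than the three required phage classes are represented."""


class UnderdeterminedError(KinquantError):
    """Too few standard points to fit the calibration line."""


class NonPositiveSlopeError(KinquantError):
    """Fitted calibration slope is not positive; fit rejected."""


class NoGfpSignalError(KinquantError):
    """No GFP component found at the requested seed point."""


class EmptyCohortError(KinquantError):
    """No includable kinetochore records to summarize."""
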