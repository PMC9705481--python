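"""Exception hierarchy for pipeline failure modes."""


class DwiharmError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(DwiharmError):
    """Volumes or masks do not share the required grid."""


class LayoutError(DwiharmError):
    """ROI geometry is inconsistent (e.g. overlapping circles)."""


class MetadataError(DwiharmError):
    """Required spacing/orientation metadata is missing or invalid."""


class DegenerateInputError(DwiharmError):
    """Input has no usable intensity range (e.g. constant volume)."""


class TemperatureRangeError(DwiharmError):
    """Phantom temperature outside the calibration validity range."""


class QAFailureError(DwiharmError):
    """Automatic phantom QA could not be performed."""


class PairingError(DwiharmError):
    """Paired analyses received unmatched (site, roi) keys."""


class FoldError(DwiharmError):
    """A cross-validation training fold is missing an organ class."""
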