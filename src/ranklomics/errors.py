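"""Exception hierarchy for ranklomics.

All package-specific failures derive from :class:`RanklomicsError` so callers
can catch the whole family; each subclass marks a distinct contract violation.
"""


class RanklomicsError(Exception):
    """Base class for all ranklomics errors."""


class ShapeMismatchError(RanklomicsError):
    """Image and mask (or two aligned arrays) have different shapes."""


class UnsupportedFormatError(RanklomicsError):
    """Input file is multi-frame, color, or otherwise not single-frame grayscale."""


class EmptyRoiError(RanklomicsError):
    """ROI mask contains no foreground pixel."""


class GeometryError(RanklomicsError):
    """Block geometry is invalid (e.g. odd block side)."""


class TooSmallRoiError(RanklomicsError):
    """ROI bounding box is smaller than a single transform block."""


class ParameterError(RanklomicsError):
    """A parameter is outside its documented domain."""


class SchemaError(RanklomicsError):
    """Feature rows or vectors do not share a consistent name set."""


class DegenerateMatrixError(RanklomicsError):
    """No valid pixel pair/run could be accumulated inside the mask."""


class DegenerateFoldError(RanklomicsError):
    """A leave-one-out training fold contains a single class."""


class SaturationError(RanklomicsError):
    """An intensity perturbation would clip or saturate the observed value range."""


class AlignmentError(RanklomicsError):
    """Predictions and labels have mismatched lengths."""
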