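"""Exception and warning types shared across the package."""


class SrcaMapError(Exception):
    """Base class for all srcamap errors."""


class RasterIOError(SrcaMapError):
    """Raised for unreadable, malformed or mismatched raster inputs."""


class CalibrationError(SrcaMapError):
    """Raised for invalid calibration state (e.g. calibrating twice)."""


class GeometryError(SrcaMapError):
    """Raised when a synthetic scenario's geometry is inconsistent."""


class ZonationError(SrcaMapError):
    """Raised when core detection or zone segmentation cannot proceed.

    May carry a ``diagnostic_map`` attribute (a label array) describing the
    offending intermediate state.
    """

    def __init__(self, message, diagnostic_map=None):
        super().__init__(message)
        self.diagnostic_map = diagnostic_map


class ClassificationError(SrcaMapError):
    """Raised when the evidence required for a life-history call is missing."""


class PipelineStageError(SrcaMapError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage, original):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


class DynamicRangeWarning(UserWarning):
    """Emitted when an input raster has less than 32-bit dynamic range."""


class DegenerateInputWarning(UserWarning):
    """Emitted for degenerate inputs handled with a documented fallback."""
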