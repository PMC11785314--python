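"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`DroughtMortError` so callers can
catch pipeline failures without masking programming errors.
"""


class DroughtMortError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(DroughtMortError, ValueError):
    """Invalid or non-finite input values."""


class InsufficientCalibrationError(DroughtMortError, ValueError):
    """Climate record too short to calibrate the drought index."""


class InsufficientSeriesError(DroughtMortError, ValueError):
    """Series shorter than the accumulation timescale."""


class DegenerateSampleError(DroughtMortError, ValueError):
    """Zero-variance sample where a distribution fit was requested."""


class FitFailureError(DroughtMortError, RuntimeError):
    """A distribution or model fit produced invalid parameters."""


class CoverageError(DroughtMortError, ValueError):
    """A child's exposure window is not covered by defined index values."""


class LinkageError(DroughtMortError, ValueError):
    """A survey cluster falls outside the climate grid."""


class ConvergenceError(DroughtMortError, RuntimeError):
    """Iterative model fit failed to converge."""
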