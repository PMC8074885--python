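"""Exception hierarchy.

Every stage raises a subclass of :class:`PostureError` so that batch
pipelines can catch analysis failures per trial without masking
programming errors.
"""


class PostureError(Exception):
    """Base class for all analysis errors raised by this package."""


class FormatError(PostureError):
    """Input file does not match the expected tabular schema."""


class SamplingError(PostureError):
    """Time grid is non-uniform or inconsistent with the stated rate."""


class ValidationError(PostureError):
    """Data fail an integrity check (missing values, bad lengths)."""


class ParameterError(PostureError):
    """A parameter is outside its valid range."""


class InsufficientDataError(PostureError):
    """Not enough samples, strides, or events for the requested analysis."""


class DetectionError(PostureError):
    """Gait event detection found no usable events."""


class EstimationError(PostureError):
    """A statistical estimate (MI, FNN, divergence curve) cannot be formed."""


class FitError(PostureError):
    """A regression has too few points or a degenerate design."""
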