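"""Exception types shared across the pipeline."""


class HepatexError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedImageError(HepatexError):
    """Image exists but is not a supported single-frame grayscale format."""


class MaskMismatchError(HepatexError):
    """Mask dimensions do not match the paired image."""


class EmptyRegionError(HepatexError):
    """An operation that needs at least one ROI pixel received none."""


class EvaluationError(HepatexError):
    """Cohort-level evaluation cannot proceed (e.g. a single-group cohort)."""


class UndefinedStatisticError(HepatexError):
    """A statistic's defining denominator is zero."""


class PhantomParameterError(HepatexError):
    """Phantom geometry or intensity parameters are invalid."""
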