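"""Exception hierarchy for the eegskip pipeline.

Every stage raises a subclass of :class:`EegSkipError` so callers can
distinguish pipeline failures from programming errors.
"""


class EegSkipError(Exception):
    """Base class for all eegskip errors."""


class ConfigurationError(EegSkipError):
    """Invalid simulation / evaluation / pipeline configuration."""


class FormatError(EegSkipError):
    """A session container on disk is missing required content."""


class PreprocessingError(EegSkipError):
    """A preprocessing pre-condition is violated (missing channel,
    segment shorter than one epoch, sampling rate too low, ...)."""


class DegenerateInputError(EegSkipError):
    """An input is degenerate for the requested statistic
    (zero variance, zero denominator, tolerance r <= 0)."""


class LengthError(EegSkipError):
    """A series is too short for the requested operation."""


class EvaluationError(EegSkipError):
    """Classifier training / validation cannot proceed
    (single-class fold, <2 subjects, degenerate split)."""
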