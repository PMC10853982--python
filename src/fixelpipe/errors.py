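"""Exception hierarchy shared across the pipeline."""


class FixelPipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FixelPipeError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(FixelPipeError):
    """Malformed input data (files, tables, templates)."""


class InvalidWarpError(FixelPipeError):
    """Warp Jacobian is singular or reflecting (det <= 0)."""


class InvalidFixelError(FixelPipeError):
    """Fixel direction is degenerate (zero or non-unit)."""


class DegenerateFitError(FixelPipeError):
    """A model fit is degenerate (zero residual variance, perfect fit)."""


class RankError(FixelPipeError):
    """Design matrix is rank deficient; message names the offending columns."""


class ClassificationError(FixelPipeError):
    """Cognitive classification impossible (missing domain scores)."""
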