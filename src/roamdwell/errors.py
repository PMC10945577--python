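"""Exception hierarchy for the roamdwell pipeline.

Every error raised on bad input derives from :class:`RoamdwellError`, so
callers (and the CLI) can distinguish pipeline validation failures from
programming errors.
"""


class RoamdwellError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RoamdwellError):
    """Input file does not match the documented dialect (e.g. missing column)."""


class ValidationError(RoamdwellError):
    """Input parsed but violates an invariant (non-monotone time, negative intensity...)."""


class EmptyInputError(RoamdwellError):
    """File or collection contained no usable records."""


class InsufficientDataError(RoamdwellError):
    """Too few observations for the requested computation."""


class ParameterError(RoamdwellError):
    """Simulation or analysis parameters outside their valid domain."""


class ConfigurationError(RoamdwellError):
    """Analysis configuration is inconsistent or incomplete."""


class DetectionError(RoamdwellError):
    """Fewer image features found than requested."""


class DegenerateDataError(RoamdwellError):
    """Data degenerate for the requested statistic (e.g. both groups constant)."""
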