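"""Exception hierarchy shared across the pipeline."""


class DyadphysError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DyadphysError):
    """A file does not conform to the expected delimited dialect."""


class ConsistencyError(DyadphysError):
    """Internally inconsistent data (e.g. header rate vs. timestamp spacing)."""


class BoundsError(DyadphysError):
    """A requested window falls outside the recorded span."""


class ParameterError(DyadphysError):
    """A synthesis or analysis parameter is outside its valid domain."""


class QualityError(DyadphysError):
    """Signal quality too poor to compute a reliable index."""


class InsufficientDataError(DyadphysError):
    """Not enough usable samples or events for the requested operation."""


class AmbiguityError(DyadphysError):
    """An alignment correlation peak is not uniquely identifiable."""


class LocalizationError(DyadphysError):
    """Phase boundaries could not be located on the physiology clock."""


class DegenerateError(DyadphysError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
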