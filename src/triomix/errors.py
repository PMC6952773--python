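"""Exception hierarchy shared across the pipeline stages."""


class TriomixError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TriomixError):
    """Invalid simulation or pipeline configuration."""


class FormatError(TriomixError):
    """A file could not be parsed; the message names the file (and line)."""


class InputError(TriomixError):
    """Input data violate a precondition of an operation."""


class ParameterError(TriomixError):
    """An operation parameter is outside its valid range."""


class NormalizationError(TriomixError):
    """A sample column cannot be normalized; the message names the sample."""


class StatisticsError(TriomixError):
    """Too few replicates, or a statistical model cannot be fitted."""


class SingularityError(StatisticsError):
    """A (near-)singular design, e.g. collinear features in a MANOVA panel."""


class DegenerateInputError(TriomixError):
    """Input with no usable variation (e.g. a constant matrix handed to PCA)."""
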