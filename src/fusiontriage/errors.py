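"""Exception hierarchy shared across the package."""


class FusionTriageError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(FusionTriageError):
    """A file could not be parsed in the declared format."""


class AnnotationError(FusionTriageError):
    """Transcript models are inconsistent or insufficient for the request."""


class CoordinateError(FusionTriageError):
    """A coordinate lies outside the space it is supposed to index."""


class ConfigError(FusionTriageError):
    """Invalid configuration value or infeasible simulation request."""
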