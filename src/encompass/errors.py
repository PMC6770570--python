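"""Exception hierarchy shared across the package."""


class EncompassError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EncompassError):
    """A structure file could not be parsed; names the offending line."""


class TopologyMismatchError(EncompassError):
    """Models of a multi-model file disagree in atom count or identity."""


class EmptySelectionError(EncompassError):
    """An atom selection resolved to zero atoms."""


class DegenerateGeometryError(EncompassError):
    """Too few or degenerate (collinear/coincident) points for an operation."""


class DegenerateSeriesError(EncompassError):
    """A time series has zero variance or is too short to analyse."""


class ConfigurationError(EncompassError):
    """Inconsistent or unresolvable analysis configuration."""


class GenerationError(EncompassError):
    """A synthetic-data generator exhausted its bounded retries."""
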