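"""Exception hierarchy shared across the pipeline."""


class GlimScreenError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(GlimScreenError, ValueError):
    """A physical measurement is outside its valid domain (e.g. height <= 0)."""


class SchemaError(GlimScreenError, ValueError):
    """A record or file is missing mandatory fields or violates the schema."""


class ValidationError(GlimScreenError, ValueError):
    """A score or count is outside its defined range."""


class CutoffDerivationError(GlimScreenError, ValueError):
    """Too few observations to derive a percentile cutoff."""


class ConfigurationError(GlimScreenError, ValueError):
    """An unknown policy, invalid grid, or otherwise bad configuration."""


class UndefinedMetricError(GlimScreenError, ZeroDivisionError):
    """A screening metric is undefined because a margin of the table is empty."""
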