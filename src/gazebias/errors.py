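"""Exception hierarchy shared across the pipeline stages."""


class GazeBiasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GazeBiasError):
    """Invalid generator, geometry or pipeline configuration."""


class DataError(GazeBiasError):
    """Malformed input data (schema, ordering or key violations)."""


class UndefinedValueError(GazeBiasError):
    """A requested quantity is mathematically undefined for this input."""
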