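"""Exception hierarchy shared across the pipeline."""


class LiftsafeError(Exception):
    """Base class for all package errors."""


class ConfigError(LiftsafeError):
    """Invalid configuration or parameter value."""


class FormatError(LiftsafeError):
    """Malformed input file (schema, dtype or sampling irregularity)."""


class DataError(LiftsafeError):
    """Structurally valid input that violates a pipeline precondition."""
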