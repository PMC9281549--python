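"""Exception hierarchy shared across the package."""


class OpfeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OpfeError):
    """A bundled resource or user configuration is malformed."""


class InvalidInputError(OpfeError, ValueError):
    """An input record violates a documented precondition."""


class StateError(OpfeError, RuntimeError):
    """An operation was called before a required prior step."""


class DegenerateInputError(OpfeError, ValueError):
    """Input is structurally valid but statistically degenerate
    (constant values, too few observations, coincident geometry)."""


class SchemaError(OpfeError, ValueError):
    """A table does not conform to the documented CSV schema."""
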