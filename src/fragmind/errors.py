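"""Exception types shared across the package."""


class FragmindError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FragmindError):
    """A catalog, grammar, or run configuration is invalid."""


class ParameterError(FragmindError):
    """An operation was called with out-of-range parameters."""


class SchemaError(FragmindError):
    """An input table is missing required columns or descriptors."""


class DegenerateTrainingError(FragmindError):
    """Training data contain only one class, or a prior of 0/1."""
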