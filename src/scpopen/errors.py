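"""Exception hierarchy shared across the package."""


class ScpopenError(ValueError):
    """Base class for all package errors."""


class ParameterError(ScpopenError):
    """A model or generator parameter is outside its valid range."""


class ConfigurationError(ScpopenError):
    """Analysis settings are inconsistent (e.g. cutoff above Nyquist)."""


class DataError(ScpopenError):
    """Input data violate an operation's preconditions."""


class SchemaError(DataError):
    """A tabular input is missing required columns."""
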