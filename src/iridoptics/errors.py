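"""Exception hierarchy shared across the package."""


class IridopticsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(IridopticsError, ValueError):
    """An argument violates a documented precondition."""


class DataError(IridopticsError, ValueError):
    """Input data are malformed or empty where content is required."""


class ConfigError(IridopticsError, ValueError):
    """A configuration file failed validation."""


class NumericalError(IridopticsError, ArithmeticError):
    """A numerical operation lost meaning (e.g. zero denominator)."""
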