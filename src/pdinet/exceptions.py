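"""Exception hierarchy shared across the package."""


class PdinetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PdinetError):
    """Invalid configuration: missing columns, unknown keys, bad formats."""


class EmptyInputError(PdinetError):
    """An input file or table contained no usable rows."""


class DomainError(PdinetError):
    """Arguments outside the mathematical domain of an operation."""


class UndefinedValueError(DomainError):
    """A statistic is undefined for the given data (e.g. constant profile)."""
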