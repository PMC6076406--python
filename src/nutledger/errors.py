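"""Exception hierarchy shared across the pipeline."""


class NutledgerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NutledgerError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(NutledgerError, ValueError):
    """An argument outside its mathematical domain (negative mass, refuse > 1, ...)."""


class SchemaError(NutledgerError, ValueError):
    """A table is missing required columns, groups, or rows."""


class LookupError_(NutledgerError, KeyError):
    """A supply item with no usable composition match."""


class UnitMismatchError(NutledgerError, ValueError):
    """Arithmetic attempted between panel entries carrying different units."""


class UndefinedStatisticError(NutledgerError, ValueError):
    """A requested statistic is undefined for the given data (zero energy, zero variance)."""
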