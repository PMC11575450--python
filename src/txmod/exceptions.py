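"""Exception hierarchy shared across the package."""


class TxmodError(Exception):
    """Base class for all package errors."""


class ParseError(TxmodError):
    """A file could not be parsed (malformed header, short line, ...)."""


class SchemaError(TxmodError):
    """A table is missing a required column."""


class ValidationError(TxmodError):
    """Parsed content violates a domain invariant (duplicates, negatives, bad enum)."""


class ConfigError(TxmodError):
    """A configuration value is inconsistent or infeasible."""


class EmptyResultError(TxmodError):
    """An operation produced an empty result where a nonempty one is required."""
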