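"""Exception hierarchy shared across the package."""


class PdxMetaError(Exception):
    """Base class for all package errors."""


class ParseError(PdxMetaError):
    """A delimited input file violates the expected layout."""


class ValidationError(PdxMetaError):
    """An in-memory object violates its invariants."""


class ConfigError(PdxMetaError):
    """A simulation or pipeline configuration is invalid."""


class EmptyResultError(PdxMetaError):
    """An operation produced an empty result where data is required."""
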