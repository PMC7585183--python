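"""Exception hierarchy shared across the pipeline stages."""


class SweepscanError(Exception):
    """Base class for all package errors."""


class ParseError(SweepscanError):
    """A malformed input record; the message names the file and line."""


class ConfigError(SweepscanError):
    """Inconsistent configuration (e.g. manifest/VCF sample mismatch)."""


class DataError(SweepscanError):
    """Input data violates a precondition of an operation."""
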