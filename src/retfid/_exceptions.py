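"""Exception types shared across the package."""


class RetfidError(Exception):
    """Base class for all package errors."""


class FormatError(RetfidError, ValueError):
    """Malformed input file or table (bad MTX, negative counts, ...)."""


class UsageError(RetfidError, ValueError):
    """An operation was called with arguments violating its contract."""


class VocabularyError(RetfidError, KeyError):
    """A raw cell-type label has no canonical mapping in strict mode."""


class ConfigError(RetfidError, ValueError):
    """Invalid simulation or pipeline configuration."""
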