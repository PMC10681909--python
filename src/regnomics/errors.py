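"""Exception hierarchy shared across modules.

Exit-code mapping used by the CLI: InputError -> 1, ConfigError -> 2,
anything else -> 3.
"""


class RegnomicsError(Exception):
    """Base class for all package errors."""


class FormatError(RegnomicsError):
    """A file on disk violates its declared format."""


class InputError(RegnomicsError):
    """In-memory inputs violate an operation's preconditions."""


class ConfigError(RegnomicsError):
    """A configuration object or file is invalid."""


class ResolutionError(RegnomicsError):
    """Numeric discretization cannot represent the requested computation."""
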