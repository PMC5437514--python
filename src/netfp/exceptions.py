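"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 1, format/data errors -> 2,
ExternalToolError -> 3.
"""


class NetfpError(Exception):
    """Base class for all package errors."""


class FormatError(NetfpError):
    """A file could not be parsed (edge list, GraphML, OBO, manifest, ...)."""


class DataError(NetfpError):
    """Parsed content violates a domain invariant (cycle, out-of-range value)."""


class ParameterError(NetfpError):
    """An operation received out-of-range or infeasible parameters."""


class ConfigError(NetfpError):
    """Invalid run configuration (unknown key, out-of-range value)."""


class ExternalToolError(NetfpError):
    """An external aligner subprocess failed; carries captured stderr."""

    def __init__(self, message: str, stderr: str = ""):
        super().__init__(message)
        self.stderr = stderr


class UndefinedICError(DataError):
    """Information content is undefined: the term annotates zero genes."""
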