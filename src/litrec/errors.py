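"""Exception hierarchy for the toolkit.

All user-facing errors derive from :class:`LitrecError` so the CLI can
separate them from genuine bugs (which surface as ordinary tracebacks).
"""


class LitrecError(Exception):
    """Base class for all toolkit errors."""


class FormatError(LitrecError):
    """A file could not be parsed in the expected format."""


class ValidationError(LitrecError):
    """Parsed content violates a domain invariant."""


class ConfigurationError(LitrecError):
    """Parameters or specs are inconsistent or infeasible."""
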