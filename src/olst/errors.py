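"""Exception hierarchy for the olst package."""


class OlstError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OlstError, ValueError):
    """A file or in-memory structure violates the documented format."""


class ConfigError(OlstError, ValueError):
    """An invalid configuration value."""


class InsufficientDataError(OlstError, ValueError):
    """Too little valid data to compute the requested quantity."""
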