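"""Exception hierarchy shared across the package."""


class PascloudError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PascloudError):
    """A file could not be parsed; the message names the line/token."""


class ValidationError(PascloudError):
    """Parsed data violates a structural invariant."""


class ConfigurationError(PascloudError):
    """A policy, design or run configuration is unusable."""
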