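"""Exception hierarchy shared across the pipeline."""


class ChromoscopeError(Exception):
    """Base class for all package errors."""


class DomainError(ChromoscopeError, ValueError):
    """A physical parameter is outside its valid domain (names the field)."""


class ConfigurationError(ChromoscopeError, ValueError):
    """Inconsistent or incomplete configuration of a pipeline stage."""


class NormalizationError(ChromoscopeError, ValueError):
    """A trace cannot be normalized (non-positive initial value)."""


class FormatError(ChromoscopeError, ValueError):
    """A file could not be parsed as the expected format."""


class InsufficientDataError(ChromoscopeError, ValueError):
    """Too few points/events/frames for the requested estimate."""
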