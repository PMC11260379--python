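"""Exception types shared across the pipeline stages."""


class EcplscError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EcplscError, ValueError):
    """An input object violates a documented invariant."""


class AlignmentError(EcplscError, ValueError):
    """Subject or region identifiers do not line up between two inputs."""


class ConfigurationError(EcplscError, ValueError):
    """A run parameter is outside the bounds of the operation consuming it."""
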