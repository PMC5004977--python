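"""Package-specific exceptions."""


class GlidebuoyError(Exception):
    """Base class for package errors."""


class InvalidStateError(GlidebuoyError, ValueError):
    """Thermodynamic inputs outside the physically supported range."""


class NonPhysicalError(GlidebuoyError, ValueError):
    """Model parameters imply a non-physical state (e.g. r*P >= 1)."""


class InsufficientDataError(GlidebuoyError, ValueError):
    """Too little data to perform an estimation step."""


class ConfigurationError(GlidebuoyError, ValueError):
    """Inconsistent pipeline configuration (e.g. missing speed channel)."""
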