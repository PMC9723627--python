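"""Exception hierarchy shared across the package."""


class IronomicsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IronomicsError, ValueError):
    """An invalid simulation/analysis configuration field."""


class EmptyMeasurementError(IronomicsError, ValueError):
    """No usable positions remain after masking."""


class InputIntegrityError(IronomicsError, ValueError):
    """Malformed or internally inconsistent input records."""


class AnnotationLookupError(IronomicsError, KeyError):
    """A record was not found in the annotation index."""


class DomainError(IronomicsError, ValueError):
    """An argument outside the mathematical domain of an operation."""
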