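"""Exception hierarchy shared across the package."""


class PhasormpError(Exception):
    """Base class for all package errors."""


class EmptySpectrumError(PhasormpError):
    """Raised when an operation requires a spectrum with positive total intensity."""


class FormatError(PhasormpError):
    """Raised when an input file does not match the declared layout."""


class ConfigurationError(PhasormpError):
    """Raised for invalid cursor sets, reference definitions, or pipeline config."""


class UnitError(PhasormpError):
    """Raised when physical-unit metadata is inconsistent between inputs."""
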