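"""Exception hierarchy shared across the pipeline stages."""


class NMFPickError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NMFPickError, ValueError):
    """Raised when input data violates an operation's preconditions."""


class ConfigurationError(NMFPickError, ValueError):
    """Raised when a configuration value is out of its admissible range."""


class FormatError(NMFPickError, OSError):
    """Raised for unreadable, truncated or unsupported image/coordinate files."""


class SimulationError(NMFPickError, RuntimeError):
    """Raised when the synthetic micrograph generator cannot satisfy its constraints."""


class EllipseFitError(NMFPickError, RuntimeError):
    """Raised when boundary points do not determine a valid ellipse."""


class CandidateRejected(NMFPickError):
    """Raised when a region candidate carries no usable border evidence."""
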