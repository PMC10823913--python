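"""Exception types shared across the package."""


class VirtualForestError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VirtualForestError, ValueError):
    """A numeric precondition was violated (e.g. non-positive dbh)."""


class ConfigurationError(VirtualForestError, ValueError):
    """Missing or inconsistent configuration (e.g. unclassified species)."""


class FittingError(VirtualForestError, RuntimeError):
    """A statistical model could not be fitted."""
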