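"""Exception hierarchy.

Exit-code mapping used by the CLI: validation errors -> 2,
configuration errors -> 3.
"""


class PhasetrackError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PhasetrackError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(InvalidInputError):
    """A shape is too small or collinear to carry a second-moment ellipse."""


class InvalidReferenceError(InvalidInputError):
    """A trajectory references a hypothesis id that does not exist."""


class InvalidCollectionError(InvalidInputError):
    """A track collection violates injectivity of the hypothesis assignment."""


class NotApplicableError(PhasetrackError):
    """An operator's applicability condition is not met (e.g. pole/lateral
    partition on a cell below the elongation cutoff)."""


class UnsupportedFormatError(InvalidInputError):
    """An image file has an axis layout the reader does not support."""


class ParseError(PhasetrackError):
    """A file could not be parsed; the message carries position information."""


class ConfigurationError(PhasetrackError):
    """A run configuration is inconsistent or infeasible."""


class ComputationError(PhasetrackError):
    """A numerical stage produced non-finite values."""
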