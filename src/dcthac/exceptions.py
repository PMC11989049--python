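"""Exception hierarchy for dcthac.

Argument-contract violations (bad shapes, out-of-range options) raise plain
``ValueError``; everything tied to data content or external files raises a
subclass of :class:`DcthacError` so callers can catch the package's errors
in one clause.
"""


class DcthacError(Exception):
    """Base class for all dcthac-specific errors."""


class InputError(DcthacError):
    """A required input file or directory is missing or unreadable."""


class ParseError(DcthacError):
    """A delimited signal file contains a token that is not a number."""


class LabelingError(DcthacError):
    """A record cannot be resolved to one of the ARR/CHF/NSR class labels."""


class FormatError(DcthacError):
    """A container (MAT file, feature CSV) violates its expected layout."""


class ConfigError(DcthacError):
    """A simulation or run configuration is invalid."""


class DataError(DcthacError):
    """Signal or feature values violate a data precondition (non-finite,
    too short, degenerate variance, ...)."""


class ConvergenceError(DcthacError):
    """An iterative solver hit its iteration cap before meeting tolerance."""
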