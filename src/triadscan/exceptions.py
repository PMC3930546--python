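"""Exception hierarchy shared across the package."""


class TriadscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TriadscanError, ValueError):
    """Invalid simulation or run configuration."""


class InsufficientDataError(TriadscanError, ValueError):
    """Too few observations for the requested computation."""


class DomainError(TriadscanError, ValueError):
    """Input outside the mathematical domain of an operation."""


class CollinearityError(TriadscanError, ValueError):
    """A variable is numerically collinear with the adjustment set."""


class UnavailableValueError(TriadscanError, ValueError):
    """A quantity cannot be computed from the given data (e.g. all-missing)."""


class JoinError(TriadscanError, ValueError):
    """Identifier sets of two tables do not overlap as required."""
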