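"""Exception hierarchy shared across the package."""


class MicrovarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MicrovarError, ValueError):
    """A file or table violates its format contract."""


class ReferentialError(MicrovarError, ValueError):
    """A cross-reference between artifacts does not resolve."""


class NewickParseError(MicrovarError, ValueError):
    """Malformed Newick input; carries the byte position of the failure."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class TreeError(MicrovarError, ValueError):
    """A tree violates a structural invariant (lengths, labels, rooting)."""


class InsufficientDataError(MicrovarError, ValueError):
    """Too few observations to compute the requested statistic."""


class DomainError(MicrovarError, ValueError):
    """Inputs are outside the mathematical domain of the statistic."""


class InsufficientCohortError(MicrovarError, ValueError):
    """The cohort is too small for quartile categorization."""
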