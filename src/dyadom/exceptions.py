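"""Exception hierarchy shared across the package."""


class DyadomError(Exception):
    """Base class for all package errors."""


class FormatError(DyadomError):
    """An input file does not match the expected tabular layout."""


class RowParseError(FormatError):
    """A specific row of an input file could not be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ValidationError(DyadomError):
    """Event data violates a structural invariant."""


class PreconditionError(DyadomError):
    """An operation was called on inputs that violate its contract."""


class AmbiguousRolesError(DyadomError):
    """Eventual dominant/subordinate roles cannot be assigned (tie or conflict)."""


class PhaseOrderingError(DyadomError):
    """Difference-criterion resolution falls after phi-criterion resolution."""


class SequenceTooShortError(DyadomError):
    """A behavior sequence has too few transitions for analysis."""


class InfeasibleSequenceError(DyadomError):
    """The label multiset admits no arrangement without adjacent repeats."""


class ConvergenceError(DyadomError):
    """An iterative fit did not reach tolerance within the iteration budget."""

    def __init__(self, message: str, discrepancy: float | None = None):
        super().__init__(message)
        self.discrepancy = discrepancy


class ConfigError(DyadomError):
    """A configuration object is internally inconsistent or infeasible."""
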