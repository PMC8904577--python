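"""Exception types shared across the package."""


class PgsAbsError(Exception):
    """Base class for all domain errors raised by this package."""


class DomainError(PgsAbsError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class MissingContextError(PgsAbsError, ValueError):
    """A metric conversion needs prevalence or case fraction that was not given."""


class DegenerateIntervalError(PgsAbsError, ValueError):
    """An interval carries (numerically) zero probability mass."""


class SolverError(PgsAbsError, RuntimeError):
    """Root-finding failed; carries bracket and tolerance diagnostics."""

    def __init__(self, message: str, bracket: tuple | None = None, tol: float | None = None):
        super().__init__(message)
        self.bracket = bracket
        self.tol = tol
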