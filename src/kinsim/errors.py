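"""Exception hierarchy.

Every error raised deliberately by the library derives from :class:`KinsimError`
so callers (and the CLI) can distinguish modelling errors from bugs.
"""


class KinsimError(Exception):
    """Base class for all kinsim errors."""


class DuplicateIdError(KinsimError):
    """An identifier is already taken in the model's flat symbol namespace."""


class UnknownIdError(KinsimError):
    """A referenced identifier does not exist."""


class DanglingReferenceError(KinsimError):
    """Removing a component would leave other components pointing at it."""


class InvalidModelError(KinsimError):
    """Model failed validation; carries the diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        msg = "; ".join(str(d) for d in self.diagnostics) or "invalid model"
        super().__init__(msg)


class UnsupportedConstructError(KinsimError):
    """An SBML construct outside the supported subset (names the construct)."""


class ParseError(KinsimError):
    """Chain-notation or MathML parse failure with location information."""

    def __init__(self, message, line=None, column=None):
        self.line = line
        self.column = column
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", col {column})" if column is not None else ")")
        super().__init__(message + loc)


class UnresolvedSymbolError(KinsimError):
    """An expression references an undeclared symbol."""


class CyclicAssignmentError(KinsimError):
    """Assignment rules form a dependency cycle."""


class StaleModelError(KinsimError):
    """The executable model is stale: the IR was edited after compilation."""


class DomainError(KinsimError):
    """A kinetic law hit a numerical domain error (e.g. log of a negative)."""

    def __init__(self, message, location=None):
        self.location = location
        super().__init__(f"{message}" + (f" in '{location}'" if location else ""))


class NonDifferentiableError(KinsimError):
    """Expression contains a node with no derivative (distribution draw)."""


class InvalidDistributionParameterError(KinsimError):
    """A distribution draw received invalid parameters (e.g. negative sd)."""


class StepFailureError(KinsimError):
    """Integrator step size underflow; reports the time it happened at."""

    def __init__(self, t, message="step size underflow"):
        self.t = t
        super().__init__(f"{message} at t={t!r}")


class NegativePropensityError(KinsimError):
    """A stochastic propensity evaluated negative (names the reaction)."""


class SingularJacobianError(KinsimError):
    """The (reduced) Jacobian is singular where a solve was required."""


class ZeroFluxScalingError(KinsimError):
    """Scaled coefficients are undefined because a flux or rate is zero."""


class NotAtSteadyStateError(KinsimError):
    """An analysis requiring a steady state was given a non-stationary point."""


class SnapshotError(KinsimError):
    """State snapshot problems: bad checksum or unsupported format version."""
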