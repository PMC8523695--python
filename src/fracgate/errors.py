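"""Exception hierarchy shared across the package."""


class FracgateError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FracgateError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class EvaluationError(FracgateError, ArithmeticError):
    """A special-function evaluation failed to converge.

    Carries the argument and parameters so the caller can diagnose which
    region of parameter space broke the evaluation strategy.
    """

    def __init__(self, message: str, *, z=None, alpha=None, beta=None):
        super().__init__(message)
        self.z = z
        self.alpha = alpha
        self.beta = beta


class SolverError(FracgateError, RuntimeError):
    """The fractional time stepper aborted (NaN/overflow in the drift)."""

    def __init__(self, message: str, *, step: int | None = None):
        super().__init__(message)
        self.step = step


class StabilityError(FracgateError, RuntimeError):
    """An explicit propagation scheme blew up; carries a stable-dt estimate."""

    def __init__(self, message: str, *, dt_max: float | None = None):
        super().__init__(message)
        self.dt_max = dt_max


class RootNotFoundError(FracgateError, RuntimeError):
    """A bracketed root search found no sign change."""


class StructureError(FracgateError, RuntimeError):
    """A rate matrix has a degenerate null space (reducible lattice)."""
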