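"""Package-wide exception types.

``PreconditionError`` signals invalid inputs or configuration (CLI exit
code 2); ``NumericalError`` signals a numerical failure inside an otherwise
valid computation, e.g. a singular covariance or a non-converged optimizer
(CLI exit code 3).
"""


class PreconditionError(ValueError):
    """An input violates a documented precondition."""


class NumericalError(RuntimeError):
    """A computation failed numerically (singularity, non-convergence, ...)."""
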