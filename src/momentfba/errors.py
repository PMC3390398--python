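"""Exception hierarchy.

Validation problems (bad files, inconsistent models, bad parameters) raise
:class:`ValidationError`; solver-side failures (infeasible, unbounded,
numerical breakdown) raise :class:`SolverError`.  The CLI maps these to
exit codes 2 and 3 respectively.
"""


class MomentError(Exception):
    """Base class for all package errors."""


class ValidationError(MomentError):
    """Input data violates a structural precondition."""


class GPRParseError(ValidationError):
    """Malformed Boolean gene-reaction rule."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class SolverError(MomentError):
    """An optimization failed (infeasible, unbounded, or solver breakdown)."""

    def __init__(self, message: str, status: str = "failed"):
        self.status = status
        super().__init__(message)
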