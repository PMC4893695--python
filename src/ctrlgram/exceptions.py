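"""Exception hierarchy.

``ContractError`` marks a violated precondition (caller bug), ``ShapeError``
a dimension mismatch, ``DivergenceError`` a numerically exploded sample path,
and ``NumericalConsistencyError`` an internal sanity check that failed (e.g. a
second-moment matrix with a significantly negative eigenvalue).
"""


class CtrlgramError(Exception):
    """Base class for all package errors."""


class ContractError(CtrlgramError, ValueError):
    """A documented precondition was violated."""


class ShapeError(ContractError):
    """Array dimensions are inconsistent; the message names the offender."""


class DivergenceError(CtrlgramError, RuntimeError):
    """A simulated path left the admissible region (non-finite or huge)."""


class NumericalConsistencyError(CtrlgramError, RuntimeError):
    """An internal numerical invariant failed beyond tolerance."""


class UnreachableDirectionError(CtrlgramError, ValueError):
    """The finite-horizon Gramian is singular; carries a null-space basis."""

    def __init__(self, message, null_basis):
        super().__init__(message)
        self.null_basis = null_basis
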