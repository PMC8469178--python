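"""Exception hierarchy shared across the package.

Validity of a proportional-vitalities model (``xi * v0(t) > t``) is a
modelling condition, not a numerical accident, so violations raise
:class:`ModelInvalidError` rather than propagating NaNs.
"""

from __future__ import annotations


class PvitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PvitError, ValueError):
    """A constructor or operation received an out-of-domain parameter."""


class ModelInvalidError(PvitError):
    """The growth condition xi*v0(t) > t fails somewhere on the evaluated range."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class NumericalError(PvitError):
    """Quadrature or root-finding failed to converge."""


class HorizonError(NumericalError):
    """A root or tail integral could not be bracketed within the allowed horizon."""


class UnsupportedFamilyError(PvitError):
    """The requested operation needs an analytic form the distribution lacks."""


class DegeneratePosteriorError(PvitError):
    """A posterior density evaluated to zero everywhere on the supplied grid."""


class BoundUnavailableError(PvitError):
    """A moment needed by a bound is infinite or non-convergent."""


class ConvergenceError(PvitError):
    """An iterative fit did not converge; carries the trajectory so far."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
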