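"""Exception types shared across the pipeline."""


class GdelayError(Exception):
    """Base class for all package errors."""


class SchemaError(GdelayError):
    """A required field or column is missing or malformed."""


class FormatError(GdelayError):
    """A container violates a structural invariant (e.g. inconsistent dt)."""


class UnevaluableRuleError(GdelayError):
    """A QC rule is enabled but the field it needs is missing."""


class InsufficientDataError(GdelayError):
    """Too few qualifying observations for the requested estimate."""


class FitError(GdelayError):
    """Nonlinear fit failed to converge or the data admit no fit."""


class IntegrationError(GdelayError):
    """The ODE integrator produced a non-finite state."""


class ProtocolMismatchError(GdelayError):
    """Two sweep families that must share a protocol do not."""


class JoinError(GdelayError):
    """Tables that must share keys have disjoint identifiers."""
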