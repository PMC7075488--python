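"""Exception hierarchy for the mfl package."""


class MflError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MflError, ValueError):
    """An argument violates a documented precondition (wrong shape, range, type)."""


class DegenerateInputError(MflError, ValueError):
    """Input is structurally valid but makes the requested quantity undefined
    (e.g. a nonpositive alpha denominator, a singular sample matrix, a zero
    contingency-table marginal)."""


class DivisionImpossibleError(DegenerateInputError):
    """A reliability of zero makes the attenuation correction undefined."""


class InvalidModelError(MflError, ValueError):
    """A factor model whose implied correlation matrix is not positive
    semi-definite (only reachable with invalid parameter combinations)."""


class InternalConsistencyError(MflError, RuntimeError):
    """A logically impossible state was reached (e.g. the double-corrected
    criterion met while the single-corrected one is violated)."""


class ValidationError(InvalidInputError):
    """A file failed schema or invariant validation; carries per-entry context.

    Parameters
    ----------
    message : str
        Human-readable summary.
    details : list of str, optional
        One entry per offending field/cell, with row/field context.
    """

    def __init__(self, message, details=None):
        self.details = list(details or [])
        if self.details:
            message = message + "\n  - " + "\n  - ".join(self.details)
        super().__init__(message)
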