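"""Exception hierarchy.

Every validation failure raises a distinct subclass of :class:`ValidationError`
so callers (and tests) can discriminate bad-input modes without string matching.
"""


class LcmsNormError(Exception):
    """Base class for all package errors."""


class ValidationError(LcmsNormError):
    """Input data violates a structural invariant."""


class DuplicateIDError(ValidationError):
    """Duplicate feature/sample identifiers or analysis orders."""


class NegativeIntensityError(ValidationError):
    """A non-missing intensity is negative."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class UnknownGroupError(ValidationError):
    """A sample group label is not one of case/control/QC."""


class ShortTraceError(ValidationError):
    """An EIC trace has fewer scans than the minimum."""


class NonMonotoneScanError(ValidationError):
    """Scan indices within an EIC trace are not strictly increasing."""


class DegenerateDataError(LcmsNormError):
    """Data admit no meaningful fit (constant column, empty stable set, ...)."""


class ConvergenceError(LcmsNormError):
    """An iterative procedure failed to converge."""
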