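"""Exception hierarchy.

All package errors derive from :class:`SasriError` so callers can catch
one base class; subclasses distinguish file-format problems, validation
of physical preconditions, and fit failures.
"""


class SasriError(Exception):
    """Base class for all package errors."""


class FormatError(SasriError):
    """A data file could not be parsed (message names the first bad line)."""


class ValidationError(SasriError):
    """Input violates a physical or structural precondition."""


class ManifestError(ValidationError):
    """Concentration-series manifest is inconsistent or too small."""


class FitError(SasriError):
    """A least-squares stage failed or produced an unphysical result."""


class NoGuinierDecayError(FitError):
    """ln I vs Q² slope is non-negative: R_g is undefined."""


class IllConditionedError(SasriError):
    """A ratio of integrals has a denominator indistinguishable from zero."""
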