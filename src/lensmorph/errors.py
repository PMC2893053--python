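"""Exception hierarchy for lensmorph."""


class LensmorphError(Exception):
    """Base class for all lensmorph errors."""


class InputError(LensmorphError):
    """An input file could not be read or decoded."""


class ValidationError(LensmorphError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateMaskError(LensmorphError):
    """A mask is empty, full, or too thin to measure."""


class InsufficientProfileError(LensmorphError):
    """A half-profile has fewer than two points."""


class InsufficientDataError(LensmorphError):
    """Too few observations for a statistical operation."""


class DegenerateVarianceError(LensmorphError):
    """Both samples have zero variance; the t statistic is undefined."""


class OneSidedMaskWarning(UserWarning):
    """One half of the section was unmeasurable; the other half was used alone."""
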