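"""Exception hierarchy for herdspan."""


class HerdspanError(Exception):
    """Base class for all herdspan errors."""


class InvalidCohortError(HerdspanError):
    """Cohort counts violate life-table structure (e.g. increasing counts)."""


class UndefinedRateError(HerdspanError):
    """A disposal rate or index cannot be formed (zero denominator)."""


class FitDomainError(HerdspanError):
    """A log-scale fit was requested on non-positive rates."""


class InsufficientDataError(HerdspanError):
    """Fewer usable points than the estimator requires."""


class SingularFitError(HerdspanError):
    """Regression design is degenerate (predictor has zero variance)."""


class InvalidInputError(HerdspanError):
    """A scalar argument is outside its admissible range."""


class InvalidCompositionError(HerdspanError):
    """A herd composition table violates its structural invariants."""


class NonInvertibleError(HerdspanError):
    """A fitted relation cannot be inverted (zero slope)."""


class ParseError(HerdspanError):
    """A delimited input file failed validation; message carries the line."""
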