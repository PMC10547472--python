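"""Exception hierarchy."""


class FacsComplexityError(Exception):
    """Base class for all package errors."""


class ValidationError(FacsComplexityError):
    """Raised when input data violate a documented invariant."""


class DegenerateInputError(FacsComplexityError):
    """Raised when an analysis is requested on data for which the
    statistic is undefined (e.g. an entropy ratio with zero expected
    entropy)."""
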