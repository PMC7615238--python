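"""Exception hierarchy shared across the package."""


class IhkaLfpError(Exception):
    """Base class for all package errors."""


class FormatError(IhkaLfpError, ValueError):
    """A file or declared metadata violates the expected format."""


class DataError(IhkaLfpError, ValueError):
    """Sample data violate an invariant (non-finite values, ...)."""


class ValidationError(IhkaLfpError, ValueError):
    """A table row or record fails validation."""


class ParameterError(IhkaLfpError, ValueError):
    """A parameter is outside its admissible range."""


class InsufficientDataError(IhkaLfpError, ValueError):
    """The signal segment is too short for the requested computation."""


class CoverageError(IhkaLfpError, ValueError):
    """The recording does not span the epochs required for analysis."""


class UndefinedBaselineError(IhkaLfpError, ValueError):
    """Percent-of-pre normalization requested with a non-positive pre rate."""
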