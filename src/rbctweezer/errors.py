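"""Exception hierarchy for the rbctweezer package."""


class RBCTweezerError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(RBCTweezerError, ValueError):
    """An argument violates a precondition (non-finite, negative, out of range)."""


class ConfigError(InvalidArgumentError):
    """A configuration object failed validation; message lists offending fields."""


class RangeError(RBCTweezerError, OverflowError):
    """A numerical term left the representable range."""


class NumericalError(RBCTweezerError, ArithmeticError):
    """A quadrature or fit failed to converge."""


class DegenerateFitError(RBCTweezerError, ValueError):
    """A calibration problem has no unique solution (e.g. all speeds zero)."""


class GeometryError(InvalidArgumentError):
    """A requested shape cannot be rendered (e.g. cell larger than frame)."""


class SegmentationError(RBCTweezerError, RuntimeError):
    """No usable foreground found in an image."""


class InsufficientDataError(RBCTweezerError, ValueError):
    """Fewer records/values than the operation requires."""


class IncompleteRecordError(RBCTweezerError, ValueError):
    """A record lacks a measurement state required by the operation."""


class UndefinedStiffnessError(RBCTweezerError, ZeroDivisionError):
    """Stiffness is undefined because the radius change is zero."""


class SchemaError(RBCTweezerError, ValueError):
    """A CSV/JSON file does not match the expected schema."""
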