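"""Exception hierarchy for paleodem."""


class PaleodemError(Exception):
    """Base class for all paleodem errors."""


class CurveFormatError(PaleodemError):
    """A calibration-curve file could not be parsed or fails validation."""


class CalibrationRangeError(PaleodemError):
    """A radiocarbon age or calendar year falls outside curve coverage."""


class SchemaError(PaleodemError):
    """An input table is missing required columns or has invalid values."""


class ValidationError(PaleodemError):
    """An input value violates a documented precondition."""


class EmptySubsetError(PaleodemError):
    """A subset predicate matched no dates."""


class DegenerateSeriesError(PaleodemError):
    """A series is constant and cannot be min-max normalized."""


class FitError(PaleodemError):
    """A model fit failed to converge; carries optimizer diagnostics."""
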