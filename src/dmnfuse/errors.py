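"""Exception types raised by the pipeline."""


class DmnfuseError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(DmnfuseError, ValueError):
    """A cohort/effect specification violates its invariants."""


class DegenerateMeasureError(DmnfuseError, ValueError):
    """A clinical measure is constant, so min-max normalization is undefined."""


class IncompleteParticipantError(DmnfuseError, ValueError):
    """A participant is missing an ROI volume or a clinical value."""


class EmptyCohortError(DmnfuseError, ValueError):
    """A cohort directory or cohort object holds no participants."""


class ShapeError(DmnfuseError, ValueError):
    """An array does not have the shape an operation requires."""


class UnsupportedShapeError(ShapeError):
    """An augmentation cannot be applied to this grid shape."""
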