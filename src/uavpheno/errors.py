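"""Exception hierarchy for the pipeline."""


class UavPhenoError(Exception):
    """Base class for all pipeline errors."""


class InvalidMetadataError(UavPhenoError):
    """Capture metadata is missing, non-finite, or out of range."""


class CalibrationError(UavPhenoError):
    """Radiometric calibration cannot be applied (e.g. non-positive denominator)."""


class DegeneratePanelError(CalibrationError):
    """The reference panel region yields a non-positive mean radiance."""


class GeometryError(UavPhenoError):
    """Invalid or degenerate geometry (zero-length line, empty polygon, ...)."""


class OutOfExtentError(GeometryError):
    """A vertex falls outside the DSM extent or on a nodata cell."""


class PointAtInfinityError(GeometryError):
    """Projected homogeneous depth is zero."""


class BehindCameraError(GeometryError):
    """Projected homogeneous depth is negative."""


class DegenerateInputError(UavPhenoError):
    """An image or histogram without enough structure for the operation."""


class ConfigurationError(UavPhenoError):
    """Unknown option value or missing configuration entry."""


class ContractError(UavPhenoError):
    """An operation precondition was violated by the caller."""


class SchemaError(UavPhenoError):
    """An interchange file does not match its expected schema."""
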