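"""Exception hierarchy shared across the pipeline."""


class EvRadiomicsError(Exception):
    """Base class for all package errors."""


class ValidationError(EvRadiomicsError):
    """Input fails a precondition (empty mask, missing column, bad value)."""


class GeometryError(ValidationError):
    """Volume and mask grids or spacings do not match."""


class ParameterError(ValidationError):
    """A configuration parameter is out of its admissible range."""


class DegenerateReferenceError(ValidationError):
    """Reference (muscle) region has zero intensity spread."""


class EmptyCooccurrenceError(ValidationError):
    """No valid voxel pair exists for the requested GLCM offset."""


class UndefinedAUCError(ValidationError):
    """ROC/AUC requested on a subset containing a single class."""
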