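"""Exception hierarchy shared across the pipeline stages."""


class StrokeRadError(Exception):
    """Base class for all package errors."""


class ConfigError(StrokeRadError):
    """Invalid or inconsistent configuration."""


class DataError(StrokeRadError):
    """Input data violates a precondition (empty mask, single-class labels, ...)."""


class GeometryError(StrokeRadError):
    """Requested lesion geometry does not fit the volume."""


class ShapeError(StrokeRadError):
    """Array shapes are incompatible."""


class ParameterError(StrokeRadError):
    """Scalar parameter out of its valid range."""


class ExclusionError(StrokeRadError):
    """Subject excluded by the lesion-size inclusion rule (< 50 voxels)."""
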