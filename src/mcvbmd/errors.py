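"""Exception hierarchy shared across the pipeline stages."""


class McvbmdError(Exception):
    """Base class for all package errors."""


class GeometryError(McvbmdError):
    """Phantom or polygon geometry is invalid (out of grid, self-intersecting...)."""


class ConfigurationError(McvbmdError):
    """Invalid cohort / training / pipeline configuration."""


class FormatError(McvbmdError):
    """Unknown or corrupt file format."""


class MissingSidecarError(FormatError):
    """A volume file lacks its calibration/metadata sidecar."""


class VOIRangeError(McvbmdError):
    """A volume-of-interest slice range does not fit the volume."""


class MetadataError(McvbmdError):
    """Required case metadata (e.g. laterality) is missing or unknown."""


class DegenerateDataError(McvbmdError):
    """Data has no variance where variance is required."""


class LeakageError(McvbmdError):
    """Validation/test information would leak into training-time statistics."""


class ShapeError(McvbmdError):
    """Array shape incompatible with a network architecture or operation."""


class EmptySegmentationError(McvbmdError):
    """A quantification was requested for an empty segmentation mask."""
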