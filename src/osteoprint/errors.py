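"""Exception hierarchy shared across the pipeline stages."""


class OsteoprintError(Exception):
    """Base class for all package errors."""


class ParameterError(OsteoprintError, ValueError):
    """A scalar/tuple argument violates its documented precondition."""


class GeometryError(OsteoprintError, ValueError):
    """A geometric object does not fit or is degenerate."""


class InvalidMetadataError(OsteoprintError, ValueError):
    """DICOM metadata is inconsistent or unusable."""


class MixedSeriesError(InvalidMetadataError):
    """A directory contains slices from more than one series."""


class SpacingError(InvalidMetadataError):
    """Inter-slice distances are non-uniform beyond tolerance."""


class MeshError(OsteoprintError, ValueError):
    """A mesh violates the structural precondition of an operation."""


class RegistrationError(OsteoprintError, ValueError):
    """Best-fit registration cannot be performed on the given inputs."""


class LabelCollisionError(OsteoprintError, ValueError):
    """Two segmentation regions carry the same structure name."""
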