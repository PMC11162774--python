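"""Exception hierarchy shared across the pipeline.

Per-structure failures in a survey batch are caught and recorded; every
error type therefore derives from :class:`RiboframeError` so the batch
driver can distinguish pipeline failures from programming errors.
"""


class RiboframeError(Exception):
    """Base class for all pipeline errors."""


class StructureFormatError(RiboframeError):
    """Coordinate file could not be parsed."""


class ModelNotFoundError(RiboframeError):
    """Requested model number absent from the file."""


class ChainUnresolvedError(RiboframeError):
    """Functional chain (16S/23S/mRNA/tRNA) could not be assigned."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates or [])


class RegisterUnresolvedError(RiboframeError):
    """The mRNA reading-frame register could not be established."""


class GeometryUnresolvedError(RiboframeError):
    """A base lacks enough ring atoms for centroid/plane geometry."""


class DegenerateFitError(RiboframeError):
    """Point set too small or collinear for a rigid superposition."""


class MeasurementUnresolvedError(RiboframeError):
    """Too few paired atoms to measure a rotation."""


class EmptySurveyError(RiboframeError):
    """Aggregation requested with zero passing records."""
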