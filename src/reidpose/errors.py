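"""Exception hierarchy.

Every error raised by the library derives from :class:`ReidPoseError` so
callers (and the CLI) can distinguish validation failures from genuine bugs.
"""


class ReidPoseError(Exception):
    """Base class for all library errors."""


class FormatParseError(ReidPoseError):
    """A file did not conform to its documented on-disk format."""


class DimensionError(ReidPoseError):
    """An embedding vector had an unexpected dimensionality."""


class ValidationError(ReidPoseError):
    """An argument violated a documented precondition."""


class ConfigurationError(ReidPoseError):
    """A scenario configuration is internally inconsistent."""


class MissingReferenceError(ReidPoseError):
    """A record referenced a detection_id with no known counterpart."""


class CardinalityError(ReidPoseError):
    """Fewer data points than clusters requested."""


class MappingError(ReidPoseError):
    """A cluster-to-label mapping was non-injective or incomplete."""


class BackendError(ReidPoseError):
    """A perception backend failed; carries the frame index for context."""

    def __init__(self, frame_index: int, message: str):
        self.frame_index = frame_index
        super().__init__(f"frame {frame_index}: {message}")


class FeatureExtractionError(ReidPoseError):
    """A skeleton lacked the anchor keypoints needed for features."""


class SchemaVersionError(ReidPoseError):
    """A trained model's feature schema does not match this library version."""


class DegenerateTrainingError(ReidPoseError):
    """Training data contained fewer than two classes."""


class InsufficientDataError(ReidPoseError):
    """Too few qualifying observations for the requested statistic."""


class CoverageError(ReidPoseError):
    """Ground truth missing for a detection that was scored."""


class SamplingError(ReidPoseError):
    """Requested more samples than available."""
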