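"""Exception hierarchy shared across the pipeline stages."""


class PalsykitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PalsykitError):
    """Malformed or empty input data."""


class ConfigurationError(PalsykitError):
    """Invalid parameter or configuration value."""


class DegenerateImageError(PalsykitError):
    """Image has no usable structure (e.g. constant intensity)."""


class DetectionError(PalsykitError):
    """A required facial feature could not be located."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class InitializationError(PalsykitError):
    """Initial-curve selection failed (empty mask after cleanup)."""


class ConvergenceError(PalsykitError):
    """Kernel scan reached the image border without a zero-sum position."""


class SegmentationError(PalsykitError):
    """Active-contour evolution produced an empty segmentation."""


class LandmarkError(PalsykitError):
    """Key-point extraction failed (e.g. empty mask)."""


class StateError(PalsykitError):
    """Operation invoked on an untrained or unready model."""


class UnresolvedGradeError(PalsykitError):
    """No lookup-table row matched and no fallback model was supplied."""
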