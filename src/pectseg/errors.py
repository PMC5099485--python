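"""Exception hierarchy for the segmentation pipeline.

Every domain failure derives from :class:`PectsegError` so callers (and the
batch CLI) can distinguish "this image could not be segmented" from a
programming error.
"""


class PectsegError(Exception):
    """Base class for all pectseg domain errors."""


class ParameterError(PectsegError, ValueError):
    """An argument is outside its documented domain."""


class UnsupportedFormatError(PectsegError):
    """The input file is readable but not a supported raster format."""


class EmptyContentError(PectsegError):
    """An operation received an image or mask with no usable content."""


class ConstantRegionError(PectsegError):
    """An intensity window cannot be computed over a constant region."""


class DegenerateThresholdError(PectsegError):
    """Otsu thresholding is undefined for a single-intensity image."""


class UnresolvedLateralityError(PectsegError):
    """Left/right breast-mass split is an exact tie; caller must supply the
    orientation explicitly."""


class NoCandidateError(PectsegError):
    """No pectoral-outline candidate survived filtering."""


class InsufficientDataError(PectsegError):
    """Fewer points than the minimal RANSAC sample size."""


class FitFailureError(PectsegError):
    """RANSAC terminated without a consensus set of at least ``n`` points."""


class UndefinedReferenceError(PectsegError):
    """Evaluation against an empty reference mask is undefined."""


class SegmentationFailure(PectsegError):
    """End-to-end segmentation failed at a named stage.

    Carries the stage name and the underlying cause so batch runs can report
    structured per-case failures instead of crashing.
    """

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"segmentation failed at stage {stage!r}: {cause}")
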