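"""Exception hierarchy for the seedling-counting pipeline.

Every stage raises a subclass of :class:`SeedlingCountError`, so callers can
catch one type at the pipeline boundary while tests can assert on the precise
failure mode.
"""


class SeedlingCountError(Exception):
    """Base class for all errors raised by this package."""


class InputError(SeedlingCountError):
    """Unreadable, undecodable or structurally invalid input."""


class FrameNotFoundError(SeedlingCountError):
    """No white reference frame could be located in the image."""


class BoundaryError(SeedlingCountError):
    """Boundary tracing failed (empty mask or ambiguous components)."""


class ChainTooShortError(SeedlingCountError):
    """Chain code shorter than the curvature neighborhood."""


class CornersNotFoundError(SeedlingCountError):
    """Fewer than four well-separated curvature maxima on the boundary."""


class DegenerateGeometryError(SeedlingCountError):
    """Collinear or degenerate point correspondences / singular transform."""


class DegenerateDataError(SeedlingCountError):
    """Observations carry no usable variance for the requested fit."""


class IdentifiabilityError(SeedlingCountError):
    """Requested model fit is not identifiable without a fixed scale."""


class UnknownVarietyError(SeedlingCountError):
    """Variety name missing from the variety-coefficient table."""


class SceneOverflowError(SeedlingCountError):
    """Requested plant count cannot be placed inside the frame interior."""


class DegenerateHistogramWarning(UserWarning):
    """Otsu thresholding received a constant map; an empty mask is returned."""


class ClampWarning(UserWarning):
    """A negative seedling-number prediction was clamped to zero."""


class PipelineStageError(SeedlingCountError):
    """Wraps a stage failure with the name of the stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
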