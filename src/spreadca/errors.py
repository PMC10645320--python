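"""Exception hierarchy shared across the package."""


class SpreadcaError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(SpreadcaError, ValueError):
    """A synthetic-landscape or parameter specification violates its invariants."""


class AlignmentError(SpreadcaError, ValueError):
    """Two raster layers that must share a geotransform do not."""


class RasterFormatError(SpreadcaError, ValueError):
    """A raster file could not be parsed."""


class CapacityError(SpreadcaError, RuntimeError):
    """A constrained sampler could not place the requested number of points.

    Carries ``achieved``, the number of points successfully placed before
    the attempt budget ran out.
    """

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class DegenerateInputError(SpreadcaError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. constant values)."""


class PipelineStageError(SpreadcaError, RuntimeError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
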