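"""Exception hierarchy for ccsmorph."""


class CCSMorphError(Exception):
    """Base class for all ccsmorph errors."""


class InvalidInputError(CCSMorphError, ValueError):
    """Non-finite, mismatched, or otherwise malformed numeric input."""


class InvalidParamsError(CCSMorphError, ValueError):
    """Generator or model parameters violate their invariants."""


class DegenerateProjectionError(CCSMorphError, ValueError):
    """A direction is (numerically) normal to the projection plane."""


class DegenerateAxisError(CCSMorphError, ValueError):
    """Landmarks coincide, so no axis direction is defined."""


class MissingLandmarkError(CCSMorphError, KeyError):
    """A required landmark is absent from the geometry."""

    def __init__(self, name: str):
        self.landmark = name
        super().__init__(f"required landmark missing: {name!r}")


class DegenerateFitError(CCSMorphError, ValueError):
    """Regression design is singular (constant regressor, too few points)."""


class SchemaError(CCSMorphError, ValueError):
    """A file or config violates its schema."""


class PipelineStageError(CCSMorphError, RuntimeError):
    """A pipeline stage failed; partial outputs keep a ``.partial`` suffix."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
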