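"""Exception hierarchy shared across the package."""


class TurstageError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TurstageError, ValueError):
    """A parameter or configuration field is invalid; the message names the field."""


class GenerationError(TurstageError, RuntimeError):
    """The phantom generator could not realize a requested geometry."""


class AnnotationError(TurstageError, ValueError):
    """A polygon annotation document is malformed or out of bounds."""


class ShapeMismatchError(TurstageError, ValueError):
    """Two arrays that must share a shape do not."""


class EmptySegmentationError(TurstageError, ValueError):
    """A label mask contains no uterus or tumor pixels where some are required."""


class SingleClassError(TurstageError, ValueError):
    """An operation needing both stage classes received only one."""


class PipelineStageError(TurstageError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
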