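"""Exception hierarchy for ifniche."""


class IfnicheError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IfnicheError, ValueError):
    """Malformed input, broken invariant, or invalid configuration."""


class FormatError(ValidationError):
    """A file did not conform to its declared format/dialect."""


class PlacementError(IfnicheError, RuntimeError):
    """A synthetic object (colony, cell, nucleus) could not be placed."""


class DegenerateInputError(ValidationError):
    """Statistically degenerate input (e.g. zero variance) for a statistic."""


class SampleSizeError(ValidationError):
    """Too few observations to perform the requested operation."""


class BasisMismatchError(ValidationError):
    """Score / threshold bases (counts vs lognorm) do not match."""


class EmptyResultError(IfnicheError, RuntimeError):
    """An operation produced an empty output where that is an error."""


class PipelineStageError(IfnicheError, RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
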