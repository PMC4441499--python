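"""Exception hierarchy shared across the pipeline."""


class ErpMicroError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ErpMicroError, ValueError):
    """A precondition on an argument was violated."""


class ShapeError(ErpMicroError, ValueError):
    """Array shapes are inconsistent with the declared geometry."""


class DegenerateConfigurationError(ErpMicroError, RuntimeError):
    """A randomized constructor could not satisfy its constraints."""


class SequencingError(ErpMicroError, RuntimeError):
    """A stimulus sequence satisfying all constraints could not be built."""


class UndefinedCorrelationError(ErpMicroError, ValueError):
    """Spatial correlation requested for a zero-variance map."""


class EmptyAverageError(ErpMicroError, ValueError):
    """An average was requested over zero kept trials or subjects."""


class IncompleteDesignError(ErpMicroError, ValueError):
    """A repeated-measures design is missing cells or is unbalanced."""


class UndefinedRateError(ErpMicroError, ValueError):
    """A behavioural rate was requested for an empty trial class."""


class FormatError(ErpMicroError, ValueError):
    """A file did not parse as the expected on-disk format."""


class PipelineStageError(ErpMicroError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
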