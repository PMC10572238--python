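"""Exception hierarchy.

``ValidationError`` subclasses ``ValueError`` so callers that only know the
standard library still catch precondition failures; ``ImageReadError``
subclasses ``IOError`` for the same reason.  ``PipelineStageError`` wraps any
stage failure inside the full pipeline and names the offending stage.
"""


class FibrespotError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FibrespotError, ValueError):
    """An input violated a documented precondition or invariant."""


class ImageReadError(FibrespotError, IOError):
    """A raster file could not be read or decoded."""


class PipelineStageError(FibrespotError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
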