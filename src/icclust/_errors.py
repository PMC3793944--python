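"""Exception hierarchy shared across the package."""


class ICCError(Exception):
    """Base class for all user-facing errors raised by icclust."""


class ValidationError(ICCError):
    """Invalid input data or parameters (bad matrix, unknown gene, ...)."""


class PipelineError(ICCError):
    """An error raised while running a pipeline stage; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
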