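"""Exception types shared across pipeline stages."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class InvalidImageError(RuntimeError):
    """Image content does not permit the requested analysis."""


class NoContourError(RuntimeError):
    """No bone contour survives tracing/filtering."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
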