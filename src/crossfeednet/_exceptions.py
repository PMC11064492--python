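"""Exception hierarchy shared across the package."""


class CrossfeednetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CrossfeednetError, ValueError):
    """Input violates a documented invariant (bad labels, self-pairs, empty sets ...)."""


class ParseError(CrossfeednetError, ValueError):
    """A file could not be parsed as the expected format."""


class CapabilityError(CrossfeednetError, RuntimeError):
    """A requested classifier family or backend is not available at runtime."""


class StageError(CrossfeednetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
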