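"""Exception hierarchy shared across the pipeline stages."""


class MfsynError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MfsynError):
    """An input file does not match the expected dialect or layout."""


class ValidationError(MfsynError):
    """A record or parameter violates a documented invariant."""


class FitError(MfsynError):
    """A model fit failed to converge or produced a degenerate component."""


class StageError(MfsynError):
    """A pipeline stage aborted; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
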