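"""Exception hierarchy shared across the package."""


class ToxpipeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ToxpipeError):
    """Malformed or inconsistent input data."""


class SizeLimitError(ToxpipeError):
    """An operation was invoked on an input larger than its hard limit."""


class UndefinedTestError(ToxpipeError):
    """A statistical test is undefined for the given data (too few
    replicates, or no variance in either group)."""


class StageError(ToxpipeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
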