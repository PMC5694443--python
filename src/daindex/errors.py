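"""Exception hierarchy for the DAI pipeline."""


class DaindexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DaindexError):
    """A configuration value or combination is invalid."""


class InputValidationError(DaindexError):
    """Input data violates the declared schema or invariants."""


class BaselineError(DaindexError):
    """An animal has too few usable baseline days; it must be excluded."""


class PipelineError(DaindexError):
    """A pipeline stage failed; carries the stage name for exit reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
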