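"""Exception hierarchy shared across the pipeline."""


class SplnetError(Exception):
    """Base class for all package errors."""


class ValidationError(SplnetError):
    """Raised when an input violates an operation's preconditions."""


class ConfigurationError(SplnetError):
    """Raised when a configuration value is out of its documented range."""


class PipelineError(SplnetError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
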