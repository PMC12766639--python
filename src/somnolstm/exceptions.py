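"""Exception hierarchy used across the toolkit."""


class SomnolstmError(Exception):
    """Base class for all package errors."""


class ValidationError(SomnolstmError):
    """An input violated a documented precondition or invariant."""


class FormatError(SomnolstmError):
    """A file could not be parsed under the documented CSV dialects."""


class IngestionError(SomnolstmError):
    """A stream is unusable (e.g. too few valid samples to interpolate)."""


class AlignmentError(SomnolstmError):
    """Streams do not overlap the hypnogram's lights window."""


class ConfigurationError(SomnolstmError):
    """A model or registry configuration is inconsistent."""


class TrainingError(SomnolstmError):
    """Model fitting failed (missing class, non-finite loss, ...)."""


class InferenceError(SomnolstmError):
    """Prediction-time shape or configuration mismatch."""


class PipelineError(SomnolstmError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
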