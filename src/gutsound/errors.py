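"""Exception types shared across the package."""


class GutSoundError(Exception):
    """Base class for package errors."""


class InvalidParameterError(GutSoundError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateSignalError(GutSoundError, ValueError):
    """A waveform is unusable (all-zero or without in-band energy)."""


class DegenerateLabelsError(GutSoundError, ValueError):
    """A label vector contains a single class where two are required."""


class SchemaError(GutSoundError, ValueError):
    """Feature names or table columns do not match the expected schema."""


class UnusableParticipantError(GutSoundError, ValueError):
    """A participant has no detected events in either recording period."""


class PipelineError(GutSoundError, RuntimeError):
    """A pipeline stage failed or its inputs are missing."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
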