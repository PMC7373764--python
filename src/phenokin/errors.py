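"""Exception hierarchy shared across the pipeline."""


class PhenokinError(Exception):
    """Base class for all package-specific errors."""


class InvalidReadingError(PhenokinError):
    """Absorbance reading is inconsistent with the calibration (far below blank)."""


class ConfigurationError(PhenokinError):
    """A required configuration key is missing or invalid."""


class InsufficientDataError(PhenokinError):
    """Too few usable points for the requested estimate or fit."""


class DegenerateDataError(PhenokinError):
    """Data carry no information about the quantity being fitted."""


class IntegrationError(PhenokinError):
    """The batch simulator produced a non-finite state."""


class PipelineStageError(PhenokinError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str, input_path: str | None = None):
        self.stage = stage
        self.input_path = input_path
        loc = f" (input: {input_path})" if input_path else ""
        super().__init__(f"stage '{stage}'{loc}: {message}")
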