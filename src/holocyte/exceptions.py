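"""Exception types shared across the pipeline."""


class HolocyteError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HolocyteError):
    """A configuration value violates its invariants."""


class GeometryOverflowError(HolocyteError):
    """A simulated cell footprint does not fit inside the image frame."""


class UnsegmentableError(HolocyteError):
    """No cell could be segmented from a phase image."""


class PipelineStageError(HolocyteError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
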