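"""Exception hierarchy shared across the pipeline stages."""


class OtogrowthError(Exception):
    """Base class for all package errors."""


class ConfigError(OtogrowthError):
    """Invalid simulation or pipeline configuration."""


class InsufficientDataError(OtogrowthError):
    """Too few observations for the requested computation."""


class SchemaError(OtogrowthError):
    """Input table violates the expected schema (e.g. a logger spans reefs)."""


class DegenerateFitError(OtogrowthError):
    """A regression cannot be fit (zero predictor variance, rank deficiency)."""


class EmptyCellError(OtogrowthError):
    """A factorial condition cell received no observations."""


class PipelineError(OtogrowthError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
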