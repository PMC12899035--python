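"""Exception hierarchy for the stabsense pipeline."""


class StabsenseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StabsenseError, ValueError):
    """An input value violates a documented precondition; names the field."""


class SchemaError(StabsenseError, ValueError):
    """A table is missing a required column or has an unparseable layout."""


class ConfigurationError(StabsenseError, ValueError):
    """A policy or configuration produces an unusable result (e.g. empty selection)."""


class TrainingError(StabsenseError, RuntimeError):
    """Model training failed (e.g. NaN loss); carries the epoch index."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class GenerationError(StabsenseError, RuntimeError):
    """Constrained sampling could not reach its quota; carries violation stats."""

    def __init__(self, message: str, violation_freq: dict | None = None):
        super().__init__(message)
        self.violation_freq = violation_freq or {}


class CompositionError(StabsenseError, ValueError):
    """The augmentation recipe cannot be satisfied with the available records."""


class PipelineError(StabsenseError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
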