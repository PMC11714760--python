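"""Exception types raised across the pipeline."""


class GrainMRIError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(GrainMRIError, ValueError):
    """Input data violates a documented contract (bad labels, shapes, ...)."""


class SizeError(GrainMRIError, ValueError):
    """A volume or instance does not fit the requested target shape."""


class PhantomSpecError(GrainMRIError, ValueError):
    """A phantom specification produces empty or inconsistent tissue classes."""


class RotationError(GrainMRIError, ValueError):
    """A rotation would clip foreground at the grid boundary."""


class PackingError(GrainMRIError, ValueError):
    """Seed placements overlap in a multi-seed packing."""


class StandardizationError(GrainMRIError, ValueError):
    """Volume cannot be standardized (constant intensity)."""


class ConfigError(GrainMRIError, ValueError):
    """Invalid configuration value."""


class StateError(GrainMRIError, RuntimeError):
    """Operation called on an object in the wrong processing state."""


class StageError(GrainMRIError, RuntimeError):
    """A pipeline stage failed; carries stage name and sample id."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for sample '{sample_id}': {cause}")
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause
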