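"""Exception hierarchy shared across the package."""


class NetmigError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NetmigError, ValueError):
    """An input violates a documented precondition or invariant."""


class RegionLookupError(NetmigError, KeyError):
    """A region name or id cannot be resolved in the atlas registry."""


class UndefinedCorrelationError(ValidationError):
    """A time-series column has zero variance, so Pearson r is undefined."""

    def __init__(self, region_names):
        self.region_names = list(region_names)
        super().__init__(
            "zero-variance BOLD series; Pearson correlation undefined for "
            f"region(s): {', '.join(self.region_names)}"
        )


class AlignmentError(ValidationError):
    """Two feature/rank structures do not share the same indexing."""


class StratificationError(ValidationError):
    """A cross-validation fold cannot contain both classes."""


class ConvergenceError(NetmigError, RuntimeError):
    """An iterative solver did not reach tolerance within its budget."""


class PipelineStageError(NetmigError, RuntimeError):
    """Wraps a failure inside `run_pipeline` with the stage name attached."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
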