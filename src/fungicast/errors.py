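"""Exception hierarchy shared across the package."""


class FungicastError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FungicastError):
    """A table is missing required columns or carries malformed ones."""


class DataValidationError(FungicastError, ValueError):
    """Values violate a dataset invariant (compositions, positivity, ordering)."""


class DomainError(FungicastError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateDataError(FungicastError, ValueError):
    """The data carry no usable structure (constant vector, zero variance)."""


class TrainingDivergenceError(FungicastError, RuntimeError):
    """Loss became non-finite during network training."""

    def __init__(self, epoch: int, message: str = ""):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class ConfigurationError(FungicastError, ValueError):
    """An invalid run configuration."""
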