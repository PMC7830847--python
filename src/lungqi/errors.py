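"""Exception types shared across the package."""


class LungQIError(Exception):
    """Base class for package errors."""


class SpecValidationError(LungQIError, ValueError):
    """A cohort specification field is invalid; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid CohortSpec field '{field}': {message}")


class CalibrationError(LungQIError):
    """A calibration target cannot be met with the available cohort."""


class ConfigurationError(LungQIError):
    """A definition references a code token absent from the dictionary."""


class DuplicatePatientError(LungQIError, ValueError):
    """Registry contains duplicate patient identifiers."""

    def __init__(self, duplicates):
        self.duplicates = list(duplicates)
        super().__init__(f"duplicate patient IDs in registry: {self.duplicates}")


class ConvergenceError(LungQIError, RuntimeError):
    """Hierarchical model estimation failed; carries the iteration trace."""

    def __init__(self, message, trace=None):
        self.trace = trace or []
        super().__init__(message)


class StageError(LungQIError, RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")
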