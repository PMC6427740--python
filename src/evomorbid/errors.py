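"""Exception hierarchy."""


class EvomorbidError(Exception):
    """Base class for package errors."""


class ValidationError(EvomorbidError, ValueError):
    """Invalid argument values or inconsistent dimensions."""


class SchemaError(EvomorbidError, KeyError):
    """Reference to a food/contaminant/column not present in the schema."""


class ParseError(EvomorbidError, ValueError):
    """Malformed on-disk dataset; carries the offending line where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class TrainingError(EvomorbidError, RuntimeError):
    """Non-finite loss or other failure during model training."""


class OptimizationError(EvomorbidError, RuntimeError):
    """Objective returned a non-finite value during optimization."""

    def __init__(self, message: str, position=None):
        self.position = position
        super().__init__(message)
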