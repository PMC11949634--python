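"""Exception hierarchy for the pipeline."""


class IGCError(Exception):
    """Base class for all package errors."""


class ConfigError(IGCError):
    """A configuration field is invalid.

    Parameters
    ----------
    field : str
        Name of the offending configuration field.
    message : str
        Human-readable description of the problem.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class DataError(IGCError):
    """A data table violates an invariant (malformed row, orphan id, ...)."""

    def __init__(self, message: str, file: str | None = None, line: int | None = None):
        self.file = file
        self.line = line
        loc = ""
        if file is not None:
            loc = f" [{file}" + (f", line {line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class IntegrityError(DataError):
    """Referential-integrity violation between tables."""


class CoverageError(DataError):
    """A required covariate stage does not cover an event (e.g. missing year network)."""


class LookupError_(IGCError):
    """A rating/score lookup for an id that has not entered the series."""


class ConvergenceError(IGCError):
    """An iterative numerical routine failed to converge."""
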