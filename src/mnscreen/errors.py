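"""Exception hierarchy for the screen-analysis pipeline."""


class MnScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(MnScreenError):
    """A table is missing a mandatory column or a config file is malformed."""


class ValidationError(MnScreenError):
    """A record or parameter violates a documented invariant."""


class RowError(ValidationError):
    """A single table row failed validation; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"row at line {line}: {message}")


class CapacityError(MnScreenError):
    """Requested layout does not fit on the allotted plates."""


class FitError(MnScreenError):
    """An optimizer failed to converge; carries best-so-far parameters."""

    def __init__(self, message: str, best_params=None, diagnostics=None):
        self.best_params = best_params
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class PipelineError(MnScreenError):
    """A stage of the orchestrated workflow could not proceed."""
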