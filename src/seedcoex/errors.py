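"""Exception hierarchy shared across the pipeline.

All errors raised deliberately by this package derive from
:class:`SeedcoexError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class SeedcoexError(Exception):
    """Base class for all errors raised by seedcoex."""


class FormatError(SeedcoexError):
    """A file does not conform to its expected tabular dialect."""


class ValidationError(SeedcoexError):
    """Parsed data violates a type invariant or a parameter is out of range."""


class UnknownGeneError(SeedcoexError):
    """A requested gene symbol is absent from the expression matrix."""


class InsufficientDataError(SeedcoexError):
    """Too few observations to carry out the requested computation."""


class UndefinedCorrelationError(SeedcoexError):
    """Correlation undefined: a vector is constant after pairwise completion."""


class DegenerateSplitError(SeedcoexError):
    """A dichotomization rule produced an empty group."""


class StageError(SeedcoexError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
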