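"""Exception hierarchy shared across the pipeline."""


class MummywebError(Exception):
    """Base class for all package errors."""


class InputError(MummywebError):
    """Invalid or inconsistent user input."""


class AlignmentError(InputError):
    """Sequences violate alignment invariants (unequal lengths, bad symbols)."""


class SchemaError(InputError):
    """A tabular input is missing required columns or has a malformed layout."""


class UndefinedDistanceError(MummywebError):
    """A pairwise distance has no comparable sites."""


class SizeError(InputError):
    """Input exceeds a documented combinatorial bound."""


class PipelineStageError(MummywebError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[stage: {stage}] {cause}")
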