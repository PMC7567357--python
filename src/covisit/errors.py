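"""Exception hierarchy shared across the package."""


class CovisitError(Exception):
    """Base class for all package errors."""


class ValidationError(CovisitError):
    """Invalid input data or configuration."""


class NotEstimableError(CovisitError):
    """A contrast cannot be estimated (empty or all-zero group)."""


class UndefinedCorrelationError(CovisitError):
    """Correlation undefined because an input vector is constant."""


class PermutationImpossibleError(CovisitError):
    """Occurrence permutation requires at least two valid stations."""


class PipelineError(CovisitError):
    """A pipeline stage failed; message is stage-labelled."""
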