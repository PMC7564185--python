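"""Exception hierarchy for the pipeline.

All errors derive from :class:`Arid1aError` so callers can catch the whole
family; most also derive from ``ValueError`` because they signal invalid
arguments or degenerate inputs.
"""


class Arid1aError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(Arid1aError, ValueError):
    """An argument violates a precondition (dimension, range, emptiness)."""


class InsufficientReplicationError(InvalidArgumentError):
    """A class has fewer than two usable samples."""


class EmptySignatureError(Arid1aError, ValueError):
    """Signature derivation retained no genes."""


class InsufficientOverlapError(Arid1aError, ValueError):
    """Fewer than two signature genes found in the target matrix."""


class DegenerateTrainingError(Arid1aError, ValueError):
    """Training compound covariate has zero pooled spread."""


class DegenerateTableError(Arid1aError, ValueError):
    """A contingency table has an all-zero row or column."""


class UndefinedCorrelationError(Arid1aError, ValueError):
    """Pearson correlation undefined (zero variance in an argument)."""


class ConvergenceError(Arid1aError, RuntimeError):
    """An iterative fit failed to converge."""


class ConfigError(Arid1aError, ValueError):
    """Pipeline configuration invalid or refers to missing files."""
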