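"""Exception types raised across the pipeline."""


class GmgaitError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(GmgaitError, ValueError):
    """An archetype/outcome specification violates its invariants."""


class MissingSeedError(GmgaitError, ValueError):
    """A generator was called without a random stream or seed."""


class SamplingRateError(GmgaitError, ValueError):
    """Sampling frequency too low for the requested band-pass."""


class DegenerateSignalError(GmgaitError, ValueError):
    """Signal cannot be amplitude-normalized (non-positive mean)."""


class InsufficientDataError(GmgaitError, ValueError):
    """Not enough strides / subjects / records for the operation."""


class PhaseDegeneracyError(GmgaitError, ValueError):
    """A gait-phase window contains no samples."""


class SchemaError(GmgaitError, ValueError):
    """Feature names or table columns do not align."""


class MissingExamError(GmgaitError, ValueError):
    """Paired E1/E2 records incomplete for one or more subjects."""


class DegenerateInputError(GmgaitError, ValueError):
    """Input carries no usable variance (e.g. identical rows)."""
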