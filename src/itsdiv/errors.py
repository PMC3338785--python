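"""Exception hierarchy.

Validation errors (bad inputs, bad parameters) and computation errors
(statistically or numerically undefined results) are kept apart so the
command-line layer can map them to distinct exit codes.
"""


class ItsDivError(Exception):
    """Base class for all package errors."""


class ValidationError(ItsDivError):
    """Invalid input data or parameters (CLI exit code 2)."""


class AlignmentError(ValidationError):
    """Malformed alignment: ragged rows, duplicate ids, bad symbols."""


class CrossReferenceError(ValidationError):
    """Metadata refers to isolates absent from the alignment."""


class ParameterError(ValidationError):
    """Out-of-range or inconsistent analysis parameter."""


class ComputationError(ItsDivError):
    """A statistic is undefined on the given data (CLI exit code 3)."""


class InsufficientSampleError(ComputationError):
    """Fewer sequences than the statistic requires."""


class NoOverlapError(ComputationError):
    """A sequence pair shares no comparable columns after pairwise deletion."""


class SaturationError(ComputationError):
    """A distance is beyond the range of the substitution model."""


class DegenerateAlignmentError(ComputationError):
    """Bootstrap resampling cannot produce enough usable replicates."""
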