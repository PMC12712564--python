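"""Exception hierarchy shared across the pipeline stages."""


class EhrShiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EhrShiftError):
    """Invalid scenario, run configuration, or parameter value."""


class SchemaError(EhrShiftError):
    """An input table is missing required columns or is empty."""


class ValidationError(EhrShiftError):
    """Input rows violate a structural invariant (orphan codes, bad ranges)."""


class MappingConflictError(EhrShiftError):
    """A code resolves to two different chapters within one coding system/axis."""


class AlignmentError(EhrShiftError):
    """Two aligned structures (grids, supports, year sets) do not match."""


class NormalizationError(EhrShiftError):
    """A probability vector does not sum to one beyond tolerance."""


class DimensionError(EhrShiftError):
    """Requested embedding dimension exceeds what the input supports."""


class EmptyBatchError(EhrShiftError):
    """A yearly batch contains no rows."""


class InsufficientBatchesError(EhrShiftError):
    """Fewer than two distinct years in the input."""


class SplitError(EhrShiftError):
    """A yearly batch cannot be split (missing class, too few rows)."""


class ThresholdError(EhrShiftError):
    """Threshold selection impossible (single-class labels)."""


class DegenerateInputError(EhrShiftError):
    """Degenerate geometry (coincident init centroids, <2 points in a year)."""


class RangeError(EhrShiftError):
    """A metric or probability lies outside its admissible range."""
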