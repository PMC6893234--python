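"""Exception hierarchy for the diametric pipeline."""


class DiametricError(Exception):
    """Base class for all package errors."""


class DimensionError(DiametricError):
    """Input array has the wrong number of dimensions."""


class GridError(DiametricError):
    """Two spatial objects do not share the same voxel grid."""


class ValidationError(DiametricError):
    """Input violates a documented contract (values, labels, uniqueness)."""


class DesignError(DiametricError):
    """A synthetic cohort design is internally inconsistent."""
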