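"""Exception hierarchy for the lctau pipeline."""


class LctauError(Exception):
    """Base class for all pipeline errors."""


class VolumeFormatError(LctauError):
    """Malformed or unreadable image file."""


class VolumeShapeError(LctauError):
    """Image does not have the required 3-D single-volume shape."""


class VolumeMismatchError(LctauError):
    """Two volumes that must share shape/affine do not."""


class MaskError(LctauError):
    """Mask contains values outside {0, 1} or is otherwise invalid."""


class SchemaError(LctauError):
    """Table is missing a required column or violates the declared schema."""


class TableParseError(LctauError):
    """A cell could not be parsed as its declared type."""

    def __init__(self, message: str, column: str | None = None,
                 rows: list | None = None):
        super().__init__(message)
        self.column = column
        self.rows = rows or []


class SimSpecError(LctauError):
    """A synthetic-data specification is internally inconsistent."""


class NormalizationError(LctauError):
    """Per-slice reference normalization cannot proceed."""

    def __init__(self, message: str, slice_index: int | None = None):
        super().__init__(message)
        self.slice_index = slice_index


class ExtractionError(LctauError):
    """LC intensity extraction cannot proceed (e.g. mask too small)."""


class SingularDesignError(LctauError):
    """Rank-deficient regression design matrix."""

    def __init__(self, message: str, collinear_columns: list | None = None):
        super().__init__(message)
        self.collinear_columns = collinear_columns or []


class DegenerateClusterError(LctauError):
    """A cluster is too small for the requested statistic."""


class InsufficientDataError(LctauError):
    """Too few complete cases for the requested model."""


class DegenerateReferenceError(LctauError):
    """A reference standard deviation is zero."""


class ConvergenceError(LctauError):
    """Iterative fit failed to converge."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class StagingError(LctauError):
    """Threshold derivation failed at a named step."""

    def __init__(self, message: str, step: str | None = None):
        super().__init__(message)
        self.step = step


class UndefinedCorrelationError(LctauError):
    """Correlation undefined (constant input after ranking)."""


class UnimodalWarning(UserWarning):
    """Gaussian-mixture components merged; cutoff undefined."""


class SmoothingWarning(UserWarning):
    """Requested smoothing FWHM is below the voxel size; skipped."""
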