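"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`FocalIndexError`
so callers (and the CLI) can distinguish input problems from bugs.
"""


class FocalIndexError(Exception):
    """Base class for all errors raised by this package."""


class ReadError(FocalIndexError):
    """A volume or mask file is missing, unreadable, or corrupt."""


class GeometryError(FocalIndexError):
    """Inconsistent DICOM series geometry or invalid phantom geometry."""


class OrientationError(FocalIndexError):
    """Orientation metadata missing or degenerate; refusing to guess."""


class CongruenceError(FocalIndexError):
    """Mask and volume grids do not match."""


class DomainError(FocalIndexError):
    """HU values outside the clipped lung domain [-1000, +100]."""


class SegmentationFailedError(FocalIndexError):
    """Lung segmentation produced an empty mask."""


class InsufficientExtentError(FocalIndexError):
    """Lung craniocaudal extent shorter than the requested slice count."""


class PartitionError(FocalIndexError):
    """Slice selection cannot be split into three equal craniocaudal groups."""


class EmptyProfileError(FocalIndexError):
    """An operation that needs a populated HU profile received an empty one."""


class GridMismatchError(FocalIndexError):
    """Two HU profiles are not on the same bin grid."""


class InsufficientSupportError(FocalIndexError):
    """Whole-lung interpolation needs at least two analysed slices."""


class UndefinedCorrelationError(FocalIndexError):
    """Correlation undefined (zero variance in an input vector)."""


class UndefinedKappaError(FocalIndexError):
    """Cohen's kappa undefined (degenerate marginals, expected agreement 1)."""


class CollinearityError(FocalIndexError):
    """Rank-deficient regression design matrix."""


class ConfigurationError(FocalIndexError):
    """Invalid configuration (phantom laws, pipeline settings)."""


class ManifestError(FocalIndexError):
    """Cohort manifest inconsistent with the scans on disk."""
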