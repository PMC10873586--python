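"""Named failure modes shared across the package."""


class CellstackError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIDError(CellstackError):
    """Gene or cell identifiers collide where uniqueness is required."""


class NegativeValueError(CellstackError):
    """An expression matrix contains negative or non-finite entries."""


class UnknownCellIDError(CellstackError):
    """A label table references a cell absent from the matrix."""


class AllZeroCellError(CellstackError):
    """A cell has zero total counts and dropping was not requested."""


class DisjointGeneSpacesError(CellstackError):
    """Train and test share no genes; alignment is impossible."""


class DegenerateSplitError(CellstackError):
    """A one-vs-rest binarization produced a single class."""


class ClassTooSmallError(CellstackError):
    """A cell type has fewer members than the requested fold count."""


class ModelIOError(CellstackError):
    """A serialized model is corrupt or from an incompatible version."""


class EmptyReportError(CellstackError):
    """An evaluation report has no per-class entries to serialize."""
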