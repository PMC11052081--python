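"""Exception types raised across the package."""


class ClppError(Exception):
    """Base class for all package-specific errors."""


class LayoutError(ClppError):
    """A plate layout violates the EcoPlate structural invariants."""


class ReadingsError(ClppError):
    """An OD readings file is malformed or inconsistent with the layout."""


class GridMismatchError(ClppError):
    """The 590 nm and 750 nm channels were not measured on the same time grid."""


class UndefinedIndexError(ClppError):
    """A diversity index is undefined for the given input (e.g. all-zero plate)."""


class TableError(ClppError):
    """An ASV count table, taxonomy or metadata file fails validation."""


class NetworkError(ClppError):
    """A co-occurrence network cannot be built or summarized as requested."""


class PipelineError(ClppError):
    """A pipeline stage failed; the message names the stage and offending input."""
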