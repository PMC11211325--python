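"""Named exceptions raised by the pipeline.

Every validation failure has a distinct class so callers (and the CLI)
can report exactly what went wrong with an input file or matrix.
"""


class FCSubtypeError(Exception):
    """Base class for all package errors."""


class RaggedRowsError(FCSubtypeError):
    """A tabular file has rows of unequal length."""


class NonNumericCellError(FCSubtypeError):
    """A cell that must be numeric could not be parsed as a float."""


class DuplicateRegionError(FCSubtypeError):
    """The same region label occurs more than once."""


class UnknownNetworkError(FCSubtypeError):
    """A parcellation row names a network outside the 7-network vocabulary."""


class SchemaError(FCSubtypeError):
    """Records passed to a table writer do not share a common schema."""


class ZeroVarianceError(FCSubtypeError):
    """A region's time series (or a covariate) is constant."""


class NonPSDError(FCSubtypeError):
    """A matrix that must be positive semi-definite is not repairable."""


class UnknownGroupError(FCSubtypeError):
    """A group label outside the recognised set was supplied."""


class DivergenceError(FCSubtypeError):
    """Autoencoder training produced a non-finite loss."""
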