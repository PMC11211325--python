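"""Per-subject Pearson connectomes and their vector representation.

A subject's connectome is the region-by-region matrix of sample Pearson
correlations between region-averaged activity time series.  Because the
matrix is symmetric with a unit diagonal, downstream clustering operates
on the strict upper triangle flattened to a vector of length n(n-1)/2.

Vectorization order is fixed as row-major over pairs (i, j) with i < j.
The clustering itself is invariant to the ordering; fixing one convention
makes the matrix <-> vector round trip exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ZeroVarianceError

__all__ = [
    "ConnectivityMatrix",
    "FCVector",
    "correlation_matrix",
    "vectorize_upper",
    "devectorize",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region correlation matrix for one subject."""

    subject_id: str
    r: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {self.r.shape}")
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(self.r.shape[0])]
        if len(self.region_labels) != self.r.shape[0]:
            raise ValueError("region_labels length does not match matrix size")

    @property
    def n(self) -> int:
        return self.r.shape[0]


@dataclass
class FCVector:
    """Strict upper triangle of a connectome, row-major over i < j."""

    subject_id: str
    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = self.n * (self.n - 1) // 2
        if self.values.shape != (expect,):
            raise ValueError(
                f"FC vector for n={self.n} must have length {expect}, got {self.values.shape}"
            )


def correlation_matrix(ts) -> ConnectivityMatrix:
    """Pearson correlation matrix of a region x time series matrix.

    Parameters
    ----------
    ts : TimeSeriesMatrix
        Region-by-timepoint matrix with unique region labels.

    Raises
    ------
    ZeroVarianceError
        If any region's series is constant; a silent r = 0 or NaN would
        distort the clustering features, so this is a hard error naming
        the offending region.
    """
    x = np.asarray(ts.values, dtype=float)
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = [ts.region_labels[i] for i in bad]
        raise ZeroVarianceError(
            f"constant time series (zero variance) for region(s): {', '.join(labels)}"
        )
    r = np.corrcoef(x)
    # guard against floating-point excursions beyond [-1, 1]
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(ts.subject_id, r, list(ts.region_labels))


def vectorize_upper(cm: ConnectivityMatrix) -> FCVector:
    """Flatten the strict upper triangle (i < j, row-major) to a vector."""
    n = cm.n
    iu = np.triu_indices(n, k=1)
    return FCVector(cm.subject_id, cm.r[iu].copy(), n)


def _n_from_triangular(length: int) -> int:
    # length = n(n-1)/2  =>  n = (1 + sqrt(1 + 8 length)) / 2
    n = int(round((1 + np.sqrt(1 + 8 * length)) / 2))
    if n * (n - 1) // 2 != length:
        raise ValueError(f"vector length {length} is not a triangular number")
    return n


def devectorize(v: FCVector | np.ndarray, diagonal_fill: float = 1.0,
                subject_id: str = "", region_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Rebuild a symmetric matrix from an upper-triangle vector."""
    if isinstance(v, FCVector):
        values, subject_id = v.values, v.subject_id
    else:
        values = np.asarray(v, dtype=float)
    n = _n_from_triangular(values.shape[0])
    r = np.full((n, n), float(diagonal_fill))
    iu = np.triu_indices(n, k=1)
    r[iu] = values
    r[(iu[1], iu[0])] = values
    return ConnectivityMatrix(subject_id, r, region_labels or [])
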