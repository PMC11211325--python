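"""Tabular I/O for time series, connectomes, parcellations and results.

All artifacts are plain-text delimited tables (TSV by default, CSV via
the ``delimiter`` argument) with a mandatory header row.  Loading is
strict: ragged rows, non-numeric cells and duplicate region labels each
raise a distinct named error rather than being silently coerced, and
row order is always preserved.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .errors import (
    DuplicateRegionError,
    NonNumericCellError,
    RaggedRowsError,
    SchemaError,
    UnknownNetworkError,
)
from .network_fc import NETWORK_NAMES

logger = logging.getLogger("fcsubtype")

__all__ = [
    "TimeSeriesMatrix",
    "load_time_series",
    "write_time_series",
    "load_matrix",
    "write_matrix",
    "load_parcellation",
    "default_parcellation",
    "load_metadata",
    "write_results_table",
]

METADATA_SCORE_COLUMNS = ("education", "mmse", "ravlt_immediate",
                          "ravlt_learning", "ravlt_forgetting")


@dataclass
class TimeSeriesMatrix:
    """Region-averaged activity series for one subject (regions x time)."""

    subject_id: str
    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D regions x timepoints matrix")
        n_regions, n_timepoints = self.values.shape
        if n_regions < 2:
            raise ValueError(f"need at least 2 regions, got {n_regions}")
        if n_timepoints < 3:
            raise ValueError(f"need at least 3 timepoints, got {n_timepoints}")
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(n_regions)]
        if len(self.region_labels) != n_regions:
            raise ValueError("region_labels length does not match row count")
        if len(set(self.region_labels)) != n_regions:
            raise DuplicateRegionError("duplicate region labels in time series")
        if not np.all(np.isfinite(self.values)):
            raise NonNumericCellError("time series contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def _read_rows(path: str | Path, delimiter: str) -> list[list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh, delimiter=delimiter) if row]


def load_time_series(path: str | Path, delimiter: str = "\t",
                     subject_id: str | None = None) -> TimeSeriesMatrix:
    """Load a regions x timepoints table; first column holds region labels.

    The header row is mandatory (its cells beyond the first are timepoint
    names and are ignored).  Rows of unequal length raise
    :class:`RaggedRowsError`; any cell that does not parse as a float
    raises :class:`NonNumericCellError` naming the offending row.
    """
    rows = _read_rows(path, delimiter)
    if len(rows) < 3:
        raise ValueError(f"{path}: need a header plus at least 2 region rows")
    header, body = rows[0], rows[1:]
    width = len(rows[0])
    labels: list[str] = []
    values = []
    for i, row in enumerate(body):
        if len(row) != width:
            raise RaggedRowsError(
                f"{path}: row {i + 2} has {len(row)} cells, expected {width}")
        labels.append(row[0])
        try:
            values.append([float(c) for c in row[1:]])
        except ValueError:
            raise NonNumericCellError(
                f"{path}: non-numeric cell in row {i + 2} (region {row[0]!r})") from None
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise DuplicateRegionError(f"{path}: duplicate region label(s) {dupes}")
    sid = subject_id if subject_id is not None else Path(path).stem
    ts = TimeSeriesMatrix(sid, np.asarray(values, dtype=float), labels)
    logger.info("loaded time series %s: %d regions x %d timepoints",
                sid, ts.n_regions, ts.n_timepoints)
    return ts


def write_time_series(ts: TimeSeriesMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(ts.values, index=ts.region_labels)
    df.columns = [f"t{j}" for j in range(ts.n_timepoints)]
    df.index.name = "region_label"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def load_matrix(path: str | Path, delimiter: str = "\t",
                subject_id: str | None = None) -> ConnectivityMatrix:
    """Load a square labelled connectivity matrix (labels in header and first column)."""
    rows = _read_rows(path, delimiter)
    header = rows[0][1:]
    labels, values = [], []
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header) + 1:
            raise RaggedRowsError(f"{path}: row {i + 2} has wrong width")
        labels.append(row[0])
        try:
            values.append([float(c) for c in row[1:]])
        except ValueError:
            raise NonNumericCellError(f"{path}: non-numeric cell in row {i + 2}") from None
    if labels != header:
        raise ValueError(f"{path}: row and column labels disagree")
    sid = subject_id if subject_id is not None else Path(path).stem
    return ConnectivityMatrix(sid, np.asarray(values), labels)


def write_matrix(cm: ConnectivityMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(cm.r, index=cm.region_labels, columns=cm.region_labels)
    df.index.name = "region_label"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


_DEFAULT_PARCELLATION = "parcellation_mmp360_yeo7_synthetic.tsv"


def load_parcellation(path: str | Path | None = None, delimiter: str = "\t",
                      strict: bool = True) -> pd.DataFrame:
    """Load a region -> network lookup table.

    Columns: ``region_label``, optional ``hemisphere`` (L/R), ``network``.
    With ``strict`` (default) the network column is restricted to the
    7-name vocabulary.  ``path=None`` loads the bundled synthetic
    360-region table (180 per hemisphere) emulating a multimodal
    parcellation mapped onto the 7 systems.
    """
    if path is None:
        with resources.as_file(resources.files("fcsubtype.data") / _DEFAULT_PARCELLATION) as p:
            df = pd.read_csv(p, sep=delimiter, comment="#")
    else:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    required = {"region_label", "network"}
    if not required <= set(df.columns):
        raise SchemaError(f"parcellation needs columns {sorted(required)}, got {list(df.columns)}")
    dupes = df["region_label"][df["region_label"].duplicated()]
    if not dupes.empty:
        raise DuplicateRegionError(f"duplicate region(s) in parcellation: {sorted(set(dupes))}")
    if strict:
        unknown = set(df["network"]) - set(NETWORK_NAMES)
        if unknown:
            raise UnknownNetworkError(
                f"unknown network name(s) {sorted(unknown)}; expected one of {NETWORK_NAMES}")
    logger.info("loaded parcellation: %d regions, %d networks",
                len(df), df["network"].nunique())
    return df.reset_index(drop=True)


def default_parcellation(n_regions: int = 60, hemispheres: bool = False,
                         network_names: tuple[str, ...] = NETWORK_NAMES) -> pd.DataFrame:
    """Build a balanced region -> network table at an arbitrary scale.

    Used for desk-scale work (default 60 regions, contiguous blocks of
    roughly equal size in the fixed network order).  The bundled
    360-region fixture is the full-scale counterpart.
    """
    k = len(network_names)
    sizes = np.full(k, n_regions // k, dtype=int)
    sizes[: n_regions % k] += 1
    if sizes.min() < 2:
        raise ValueError(f"{n_regions} regions cannot give every network >= 2 regions")
    rows = []
    i = 0
    for net, size in zip(network_names, sizes):
        for _ in range(size):
            rec = {"region_label": f"R{i:03d}", "network": net}
            if hemispheres:
                rec["hemisphere"] = "L" if i % 2 == 0 else "R"
            i += 1
            rows.append(rec)
    cols = ["region_label"] + (["hemisphere"] if hemispheres else []) + ["network"]
    return pd.DataFrame(rows)[cols]


def load_metadata(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Load the subject metadata table; missing values allowed only in score columns."""
    df = pd.read_csv(path, sep=delimiter)
    if df["subject_id"].duplicated().any():
        raise DuplicateRegionError("duplicate subject_id in metadata")
    core = [c for c in ("subject_id", "group", "age", "sex") if c in df.columns]
    if df[core].isna().any().any():
        raise SchemaError("missing values in non-score metadata columns")
    return df


def write_results_table(rows: list[dict], path: str | Path, delimiter: str = "\t",
                        float_precision: int = 6, columns: list[str] | None = None) -> None:
    """Write homogeneous records with deterministic column order.

    Column order follows the first record (or ``columns``); floats are
    serialised with ``float_precision`` significant digits.  An empty
    record list yields a header-only file (header from ``columns``, or
    empty when no schema is known).
    """
    if isinstance(rows, pd.DataFrame):
        rows.to_csv(path, sep=delimiter, index=False,
                    float_format=f"%.{float_precision}g")
        return
    if not rows:
        Path(path).write_text(delimiter.join(columns) + "\n" if columns else "")
        return
    keys = columns if columns is not None else list(rows[0])
    for i, rec in enumerate(rows):
        if set(rec) != set(keys):
            raise SchemaError(f"record {i} keys {sorted(rec)} differ from schema {sorted(keys)}")
    pd.DataFrame(rows, columns=keys).to_csv(
        path, sep=delimiter, index=False, float_format=f"%.{float_precision}g")
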