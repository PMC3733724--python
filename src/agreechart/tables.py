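"""Square ordinal contingency tables: validation, I/O, and basic manipulation.

A :class:`ContingencyTable` holds the k x k cross-classification of n items
rated independently by two raters (or measurement methods) on the same
ordered k-category scale.  Cell ``n_ij`` counts the items placed in row
category ``i`` by the row rater and column category ``j`` by the column
rater.  The category order is meaningful: all partial-agreement machinery
downstream measures disagreement by index distance ``|i - j|``, which is
only defensible on an ordinal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "TableError",
    "NonSquareError",
    "InvalidCountError",
    "EmptyTableError",
    "LabelError",
    "MarginalMismatchError",
    "validate",
    "read_csv",
    "write_csv",
    "transpose",
    "from_ratings",
]


class TableError(ValueError):
    """Base class for contingency-table validation failures."""


class NonSquareError(TableError):
    """Raised when the count matrix is not square with k >= 2."""


class InvalidCountError(TableError):
    """Raised when a cell is negative or not an integer."""


class EmptyTableError(TableError):
    """Raised when the table total is zero."""


class LabelError(TableError):
    """Raised when category labels are missing, duplicated, or miscounted."""


class MarginalMismatchError(TableError):
    """Raised when a CSV 'Total' row/column disagrees with the cells."""


@dataclass(frozen=True)
class ContingencyTable:
    """Validated square integer contingency table of paired ordinal ratings.

    Parameters
    ----------
    counts : ndarray of shape (k, k)
        Non-negative integer cell counts ``n_ij``.
    labels : tuple of str
        Ordered category names, one per row/column.
    row_rater, col_rater : str
        Free-text names of the raters on rows and columns.
    """

    counts: np.ndarray
    labels: tuple[str, ...]
    row_rater: str = "rater A"
    col_rater: str = "rater B"
    _marginals: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise NonSquareError(
                f"count matrix must be square, got shape {counts.shape}"
            )
        if counts.shape[0] < 2:
            raise NonSquareError("need at least 2 categories")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(np.asarray(counts, dtype=float))
            if not np.array_equal(rounded, np.asarray(counts, dtype=float)):
                bad = np.argwhere(rounded != np.asarray(counts, dtype=float))[0]
                raise InvalidCountError(
                    f"cell ({bad[0]}, {bad[1]}) is not an integer"
                )
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise InvalidCountError(
                f"cell ({bad[0]}, {bad[1]}) is negative: {counts[bad[0], bad[1]]}"
            )
        if counts.sum() == 0:
            raise EmptyTableError("table total is zero")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != counts.shape[0]:
            raise LabelError(
                f"{len(labels)} labels supplied for a {counts.shape[0]}-category table"
            )
        if len(set(labels)) != len(labels):
            raise LabelError(f"duplicate category labels: {labels}")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", labels)
        self._marginals["row"] = counts.sum(axis=1)
        self._marginals["col"] = counts.sum(axis=0)
        self._marginals["n"] = int(counts.sum())

    # -- derived quantities -------------------------------------------------

    @property
    def k(self) -> int:
        """Number of categories."""
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        """Total number of rated items."""
        return self._marginals["n"]

    @property
    def row_totals(self) -> np.ndarray:
        """Row marginals ``n_i.`` (items per category for the row rater)."""
        return self._marginals["row"]

    @property
    def col_totals(self) -> np.ndarray:
        """Column marginals ``n_.j`` (items per category for the column rater)."""
        return self._marginals["col"]

    @property
    def diagonal(self) -> np.ndarray:
        """Exact-agreement counts ``n_ii``."""
        return np.diag(self.counts)

    # -- manipulation -------------------------------------------------------

    def transpose(self) -> "ContingencyTable":
        """Exchange the raters: rows become columns and vice versa."""
        return ContingencyTable(
            self.counts.T.copy(),
            self.labels,
            row_rater=self.col_rater,
            col_rater=self.row_rater,
        )

    def scaled(self, c: int) -> "ContingencyTable":
        """Multiply every cell by a positive integer ``c``."""
        if c < 1:
            raise InvalidCountError("scale factor must be a positive integer")
        return ContingencyTable(
            self.counts * int(c), self.labels, self.row_rater, self.col_rater
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.labels), columns=list(self.labels)
        )

    def __str__(self) -> str:
        df = self.to_dataframe()
        return f"{self.row_rater} (rows) vs {self.col_rater} (cols)\n{df}"


def validate(
    counts: Sequence[Sequence[int]] | np.ndarray,
    labels: Sequence[str] | None = None,
    row_rater: str = "rater A",
    col_rater: str = "rater B",
) -> ContingencyTable:
    """Validate a raw count matrix and wrap it as a :class:`ContingencyTable`.

    If ``labels`` is omitted, categories are named ``"1" .. "k"``.
    """
    arr = np.asarray(counts)
    if labels is None:
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise NonSquareError(f"count matrix must be square, got shape {arr.shape}")
        labels = [str(i + 1) for i in range(arr.shape[0])]
    return ContingencyTable(arr, tuple(labels), row_rater, col_rater)


_TOTAL_NAMES = {"total", "sum", "all"}


def _is_total_label(label: object) -> bool:
    return str(label).strip().lower() in _TOTAL_NAMES


def read_csv(path: str | Path, row_rater: str = "rater A",
             col_rater: str = "rater B") -> ContingencyTable:
    """Read a contingency table from CSV.

    Expected layout: first row holds the column category labels, first
    column the row category labels, integer cells.  A trailing ``Total``
    row and/or column is detected, cross-checked against the computed
    marginals, and stripped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableError(f"malformed CSV {path}: {exc}") from exc

    total_row = None
    total_col = None
    if len(df.index) and _is_total_label(df.index[-1]):
        total_row = df.iloc[-1]
        df = df.iloc[:-1]
    if len(df.columns) and _is_total_label(df.columns[-1]):
        total_col = df.iloc[:, -1]
        df = df.iloc[:, :-1]

    for i, row in enumerate(df.itertuples(index=False)):
        for j, v in enumerate(row):
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise InvalidCountError(
                    f"{path}: non-numeric cell at row '{df.index[i]}', "
                    f"column '{df.columns[j]}': {v!r}"
                ) from None
            if fv != int(fv):
                raise InvalidCountError(
                    f"{path}: non-integer cell at row '{df.index[i]}', "
                    f"column '{df.columns[j]}': {v!r}"
                )

    counts = df.to_numpy(dtype=np.int64)
    if total_row is not None:
        stated = total_row.iloc[: counts.shape[1]].to_numpy(dtype=np.int64)
        if not np.array_equal(stated, counts.sum(axis=0)):
            raise MarginalMismatchError(
                f"{path}: 'Total' row {stated.tolist()} disagrees with computed "
                f"column sums {counts.sum(axis=0).tolist()}"
            )
    if total_col is not None:
        stated = total_col.iloc[: counts.shape[0]].to_numpy(dtype=np.int64)
        if not np.array_equal(stated, counts.sum(axis=1)):
            raise MarginalMismatchError(
                f"{path}: 'Total' column {stated.tolist()} disagrees with computed "
                f"row sums {counts.sum(axis=1).tolist()}"
            )

    labels = [str(l) for l in df.index]
    if labels != [str(c) for c in df.columns]:
        raise LabelError(
            f"{path}: row labels {labels} differ from column labels "
            f"{[str(c) for c in df.columns]}"
        )
    return ContingencyTable(counts, tuple(labels), row_rater, col_rater)


def write_csv(table: ContingencyTable, path: str | Path) -> None:
    """Write a table to CSV in the layout :func:`read_csv` expects."""
    table.to_dataframe().to_csv(path)


def transpose(table: ContingencyTable) -> ContingencyTable:
    """Functional alias for :meth:`ContingencyTable.transpose`."""
    return table.transpose()


def from_ratings(
    ratings_a: Sequence, ratings_b: Sequence,
    labels: Sequence[str] | None = None,
    row_rater: str = "rater A", col_rater: str = "rater B",
) -> ContingencyTable:
    """Tabulate two aligned per-subject rating sequences into a table.

    ``labels`` fixes the category order; if omitted, the sorted union of
    observed values is used (adequate only when lexical order matches the
    ordinal scale).
    """
    a = pd.Series(ratings_a)
    b = pd.Series(ratings_b)
    if len(a) != len(b):
        raise TableError(f"rating sequences differ in length: {len(a)} vs {len(b)}")
    if labels is None:
        labels = sorted(set(a.astype(str)) | set(b.astype(str)))
    labels = [str(l) for l in labels]
    cat = pd.CategoricalDtype(categories=labels, ordered=True)
    xt = pd.crosstab(a.astype(str).astype(cat), b.astype(str).astype(cat),
                     dropna=False)
    return ContingencyTable(xt.to_numpy(), tuple(labels), row_rater, col_rater)
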