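"""Delimited-text matrix I/O with row/column identifiers.

Native format: TSV (or CSV by extension) with a header row of column ids and
a first column of row ids. "NA" or empty cells encode missing values, which
are only legal in outcome matrices. Values are written with 17 significant
digits so write-read round trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, allow_missing: bool = False):
    """Read a delimited matrix; returns (values, row_ids, col_ids).

    ``allow_missing=False`` (the predictor contract) raises on any NA cell,
    naming the offending row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=_sep(path),
            index_col=0,
            na_values=["NA"],
            keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate row ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate column ids: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from exc
    if not allow_missing and np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(
            f"{path}: missing value at row {df.index[i]!r} (line {i + 2}), "
            f"column {df.columns[j]!r}"
        )
    return values, [str(x) for x in df.index], [str(x) for x in df.columns]


def write_matrix(path: str | Path, values, row_ids, col_ids, id_name: str = "id"):
    """Write a matrix with ids; NaN values are written as "NA"."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values, index=list(row_ids), columns=list(col_ids))
    df.index.name = id_name
    df.to_csv(path, sep=_sep(path), na_rep="NA", float_format="%.17g")
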