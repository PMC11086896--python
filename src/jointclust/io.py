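"""Readers and writers for the pipeline's plain-text artifacts.

All matrices travel as delimited text with a header row and an index
column of item ids ("X:<i>" / "Y:<j>" / "O:origin"); labels and datasets
as flat CSVs; configs as YAML/JSON.  Everything written here is re-readable
by the same module (round-trip property).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_dataset",
    "read_dataset_items",
    "write_predicted_labels",
]


def read_matrix(
    path: str | Path, expect_square_distance: bool = False
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labeled numeric matrix (header row + index column).

    Returns (values, row_ids, col_ids).  With ``expect_square_distance``
    the matrix is validated as a distance matrix (square, symmetric, zero
    diagonal).  Parse problems raise with the offending row/column named.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    bad = df.columns[df.dtypes == object]
    for col in bad:
        coerced = pd.to_numeric(df[col], errors="coerce")
        culprits = df.index[coerced.isna() & df[col].notna()]
        if len(culprits):
            raise ValueError(
                f"{path}: non-numeric cell at row {culprits[0]!r}, column {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing/NaN value in row {row!r}")
    values = df.to_numpy(dtype=float)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if expect_square_distance:
        if values.shape[0] != values.shape[1]:
            raise ValueError(f"{path}: declared distance matrix is not square")
        if not np.allclose(values, values.T):
            raise ValueError(f"{path}: declared distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError(f"{path}: declared distance matrix has nonzero diagonal")
    return values, row_ids, col_ids


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    row_ids: list[str],
    columns: list[str] | None = None,
) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    values = np.asarray(values)
    if columns is None:
        columns = list(row_ids) if values.shape[1] == len(row_ids) else [
            f"c{i}" for i in range(values.shape[1])
        ]
    df = pd.DataFrame(values, index=list(row_ids), columns=columns)
    df.to_csv(path, sep=sep)


def write_dataset(out_dir: str | Path, pair) -> None:
    """One CSV per dataset (rows = items, columns = observations or the
    flattened moment time-course) plus a labels CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, items in (("X", pair.X_items), ("Y", pair.Y_items)):
        rows = [np.asarray(it, dtype=float).ravel() for it in items]
        width = max(r.size for r in rows)
        mat = np.full((len(rows), width), np.nan)
        for i, r in enumerate(rows):
            mat[i, : r.size] = r
        ids = [f"{name}:{i}" for i in range(len(rows))]
        write_matrix(out_dir / f"data_{name}.csv", mat,
                     ids, [f"obs{i}" for i in range(width)])
    labels = pd.DataFrame(
        {
            "item_id": [f"X:{i}" for i in range(pair.m)]
            + [f"Y:{j}" for j in range(pair.n)],
            "dataset": ["X"] * pair.m + ["Y"] * pair.n,
            "true_label": np.concatenate([pair.true_labels_X, pair.true_labels_Y]),
            "pairing_id": np.concatenate([pair.pairing_ids_X, pair.pairing_ids_Y]),
        }
    )
    labels.to_csv(out_dir / "labels.csv", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"item_id", "dataset", "true_label", "pairing_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: labels file must have columns {sorted(required)}")
    return df


def read_dataset_items(out_dir: str | Path) -> tuple[list[np.ndarray], list[np.ndarray]]:
    out_dir = Path(out_dir)
    items = []
    for name in ("X", "Y"):
        # read directly: NaN cells are legitimate right-padding when item
        # lengths differ, which read_matrix would reject
        df = pd.read_csv(out_dir / f"data_{name}.csv", index_col=0)
        values = df.to_numpy(dtype=float)
        items.append([row[~np.isnan(row)] for row in values])
    return items[0], items[1]


def write_predicted_labels(path: str | Path, item_ids: list[str], labels: np.ndarray) -> None:
    pd.DataFrame({"item_id": item_ids, "predicted_label": np.asarray(labels)}).to_csv(
        path, index=False
    )
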