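"""Reading and writing binary VA datasets.

Two dialects are supported:

* the repository CSV dialect — a header row, an optional id column, one
  cause column, and binary symptom columns (configurable yes/no tokens);
* the InterVA-4 input dialect — same column layout but a present symptom
  is written ``Y`` and an absent one an empty cell (write + re-read).

Missing cells are coded 0 (symptom absent): the binary recoding of VA
answers admits only present/absent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import VADataset

__all__ = [
    "DEFAULT_YES_TOKENS",
    "DEFAULT_NO_TOKENS",
    "read_dataset",
    "write_dataset",
    "to_interva_rows",
    "write_interva",
]

DEFAULT_YES_TOKENS = frozenset({"1", "Y", "Yes", "y", "yes", "YES"})
DEFAULT_NO_TOKENS = frozenset({"0", "", "N", "No", "n", "no", "NO"})


class VAParseError(ValueError):
    """Malformed cell or structurally invalid VA file."""


def _coerce_binary(df: pd.DataFrame, yes_tokens, no_tokens) -> np.ndarray:
    X = np.empty(df.shape, dtype=np.int8)
    cols = list(df.columns)
    for j, col in enumerate(cols):
        vals = df[col].astype(object).where(df[col].notna(), "")
        for i, v in enumerate(vals):
            tok = str(v).strip()
            # pandas may parse "1" as int/float; normalise 1.0 -> "1"
            if tok.endswith(".0"):
                tok = tok[:-2]
            if tok in yes_tokens:
                X[i, j] = 1
            elif tok in no_tokens:
                X[i, j] = 0
            else:
                raise VAParseError(
                    f"unparseable symptom value {v!r} at row {i}, column {col!r}"
                )
    return X


def read_dataset(
    path,
    cause_column: str = "cause",
    id_column: str = "id",
    yes_tokens=DEFAULT_YES_TOKENS,
    no_tokens=DEFAULT_NO_TOKENS,
) -> VADataset:
    """Read a binary VA dataset from CSV.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row. Columns other than ``id_column`` and
        ``cause_column`` are binary symptoms; column order is preserved.
    cause_column : str
        Name of the cause-of-death label column (required).
    id_column : str
        Name of the record-id column; if absent, row numbers are used.
    yes_tokens, no_tokens : collections of str
        Cell tokens mapped to 1 and 0. Empty/missing cells map to 0.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    if df.shape[0] == 0:
        raise VAParseError(f"{path}: no records")
    if cause_column not in df.columns:
        raise VAParseError(f"{path}: cause column {cause_column!r} not found")
    y = df[cause_column].astype(str).str.strip().to_numpy(dtype=object)
    if (y == "").any():
        bad = int(np.flatnonzero(y == "")[0])
        raise VAParseError(f"{path}: empty cause label at row {bad}")
    if id_column in df.columns:
        record_ids = df[id_column].astype(str).tolist()
    else:
        record_ids = [str(i) for i in range(len(df))]
    sym = df.drop(columns=[c for c in (id_column, cause_column) if c in df.columns])
    if sym.shape[1] == 0:
        raise VAParseError(f"{path}: no symptom columns")
    X = _coerce_binary(sym, frozenset(yes_tokens), frozenset(no_tokens))
    return VADataset(
        record_ids=record_ids,
        symptom_names=list(sym.columns),
        X=X,
        y=y,
    )


def write_dataset(
    ds: VADataset, path, cause_column: str = "cause", id_column: str = "id"
) -> None:
    """Write a VADataset in the repository CSV dialect (0/1 cells)."""
    ds.to_frame(cause_column=cause_column, id_column=id_column).to_csv(path, index=False)


def to_interva_rows(ds: VADataset) -> pd.DataFrame:
    """Recode the symptom matrix in the InterVA-4 input dialect.

    Every 1 becomes ``"Y"`` and every 0 an empty string; the header is
    the symptom names and the index the record ids. Shape is preserved.
    """
    cells = np.where(ds.X == 1, "Y", "")
    return pd.DataFrame(cells, columns=ds.symptom_names, index=ds.record_ids)


def write_interva(
    ds: VADataset, path, cause_column: str = "cause", id_column: str = "id"
) -> None:
    """Write the dataset as an InterVA-4 style CSV (Y/empty cells)."""
    df = to_interva_rows(ds).reset_index(names=id_column)
    df[cause_column] = ds.y
    df.to_csv(path, index=False)
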