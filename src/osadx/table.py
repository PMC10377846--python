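"""Labeled feature table with per-column type metadata.

The central exchange type of the package: a samples x features grid of
numeric values and nominal level codes, a binary label vector, and a
``numeric``/``nominal`` flag per column.  Missing cells are NaN; labels
are never missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NUMERIC = "numeric"
NOMINAL = "nominal"

__all__ = ["LabeledTable", "NUMERIC", "NOMINAL", "read_csv", "write_csv"]


@dataclass
class LabeledTable:
    """Feature matrix plus binary labels.

    Parameters
    ----------
    X : pandas.DataFrame
        Float-valued frame.  Nominal columns hold integer level codes
        (stored as floats); missing cells are NaN.
    y : numpy.ndarray
        Binary label vector, one entry per row of ``X``; 1 means apnea.
    types : tuple of str
        Per-column flag, ``"numeric"`` or ``"nominal"``, aligned with
        ``X.columns``.
    levels : dict
        Optional mapping of nominal column name to its ordered list of
        level labels (code ``i`` means ``levels[col][i]``).
    """

    X: pd.DataFrame
    y: np.ndarray
    types: tuple
    levels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.types = tuple(self.types)
        if len(self.types) != self.X.shape[1]:
            raise ValueError(
                f"types length {len(self.types)} != column count {self.X.shape[1]}"
            )
        bad = set(self.types) - {NUMERIC, NOMINAL}
        if bad:
            raise ValueError(f"unknown column types: {sorted(bad)}")
        if len(self.y) != self.X.shape[0]:
            raise ValueError(
                f"label length {len(self.y)} != row count {self.X.shape[0]}"
            )
        if pd.isna(self.y).any():
            raise ValueError("labels must not contain missing values")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list:
        return list(self.X.columns)

    def type_of(self, column: str) -> str:
        return self.types[self.column_names.index(column)]

    def numeric_columns(self) -> list:
        return [c for c, t in zip(self.X.columns, self.types) if t == NUMERIC]

    def nominal_columns(self) -> list:
        return [c for c, t in zip(self.X.columns, self.types) if t == NOMINAL]

    def missing_mask(self) -> pd.DataFrame:
        return self.X.isna()

    def copy(self) -> "LabeledTable":
        return LabeledTable(
            self.X.copy(), self.y.copy(), self.types, dict(self.levels)
        )

    # ------------------------------------------------------------------
    def select_features(self, mask) -> "LabeledTable":
        """Restrict to the columns where ``mask`` is 1/True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_features:
            raise ValueError(
                f"mask length {mask.size} != feature count {self.n_features}"
            )
        cols = [c for c, keep in zip(self.X.columns, mask) if keep]
        types = tuple(t for t, keep in zip(self.types, mask) if keep)
        levels = {c: v for c, v in self.levels.items() if c in cols}
        return LabeledTable(self.X[cols].copy(), self.y.copy(), types, levels)

    def select_rows(self, idx) -> "LabeledTable":
        idx = np.asarray(idx)
        return LabeledTable(
            self.X.iloc[idx].reset_index(drop=True),
            self.y[idx],
            self.types,
            dict(self.levels),
        )

    def drop_column(self, column: str) -> "LabeledTable":
        i = self.column_names.index(column)
        types = tuple(t for j, t in enumerate(self.types) if j != i)
        levels = {c: v for c, v in self.levels.items() if c != column}
        return LabeledTable(
            self.X.drop(columns=[column]), self.y.copy(), types, levels
        )

    def to_matrix(self) -> np.ndarray:
        """Dense float matrix view (nominal columns as level codes)."""
        return self.X.to_numpy(dtype=float)

    # ------------------------------------------------------------------
    def equals(self, other: "LabeledTable") -> bool:
        return (
            self.types == other.types
            and list(self.X.columns) == list(other.X.columns)
            and np.array_equal(self.y, other.y)
            and self.X.equals(other.X)
        )


def write_csv(table: LabeledTable, path, label_column: str = "label",
              planted_mask=None) -> None:
    """Write a table as CSV (empty cell = missing, last column = label).

    A ``<path>.meta.json`` sidecar records per-column types, nominal
    levels and, optionally, the planted ground-truth mask.
    """
    path = Path(path)
    out = table.X.copy()
    out[label_column] = table.y
    out.to_csv(path, index=False)
    meta = {
        "columns": table.column_names,
        "types": list(table.types),
        "levels": {k: list(v) for k, v in table.levels.items()},
        "label_column": label_column,
    }
    if planted_mask is not None:
        meta["planted_mask"] = [int(b) for b in np.asarray(planted_mask)]
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_csv(path, label_column: str = None) -> LabeledTable:
    """Read a table written by :func:`write_csv`.

    Without a sidecar, every column is treated as numeric and
    ``label_column`` defaults to the last column.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        label_column = label_column or meta["label_column"]
        types = tuple(meta["types"])
        levels = {k: list(v) for k, v in meta["levels"].items()}
    else:
        label_column = label_column or frame.columns[-1]
        types = tuple(NUMERIC for c in frame.columns if c != label_column)
        levels = {}
    y = frame[label_column].to_numpy(dtype=int)
    X = frame.drop(columns=[label_column]).astype(float)
    return LabeledTable(X, y, types, levels)
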