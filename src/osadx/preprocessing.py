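"""Cleaning, imputation, rescaling and demographic grouping.

Order used by the default pipeline: drop sparse columns/rows, impute
(mean for numeric, mode for nominal), min-max rescale numeric columns
to [0, 1].  Grouping splits a table by race, sex, or an age threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table import NOMINAL, NUMERIC, LabeledTable

__all__ = [
    "NormalizationParams",
    "ImputationParams",
    "GroupSpec",
    "drop_sparse",
    "fit_imputer",
    "apply_imputer",
    "impute",
    "fit_normalizer",
    "apply_normalizer",
    "min_max_normalize",
    "epworth_category",
    "split_groups",
    "preprocess",
]

EPWORTH_BANDS = [
    (0, 5, "lower_normal"),
    (6, 10, "higher_normal"),
    (11, 12, "mild"),
    (13, 15, "moderate"),
    (16, 24, "significant"),
]


# ----------------------------------------------------------------------
# sparse removal
# ----------------------------------------------------------------------

def drop_sparse(table: LabeledTable, threshold: float = 0.5) -> LabeledTable:
    """Remove columns, then rows, whose missing fraction exceeds ``threshold``.

    The inequality is strict: a column with exactly ``threshold``
    missing is retained.  Labels are exempt (they are never missing).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    missing = table.X.isna()
    col_frac = missing.mean(axis=0)
    keep_cols = col_frac.to_numpy() <= threshold
    if not keep_cols.any():
        raise ValueError("all columns exceed the sparsity threshold; input unusable")
    out = table.select_features(keep_cols)
    row_frac = out.X.isna().mean(axis=1).to_numpy()
    keep_rows = np.flatnonzero(row_frac <= threshold)
    return out.select_rows(keep_rows)


# ----------------------------------------------------------------------
# imputation
# ----------------------------------------------------------------------

@dataclass
class ImputationParams:
    """Per-column fill value: observed mean (numeric) or mode (nominal)."""

    fill: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.fill, indent=2))

    @classmethod
    def from_json(cls, path) -> "ImputationParams":
        return cls(json.loads(Path(path).read_text()))


def fit_imputer(table: LabeledTable) -> ImputationParams:
    fill = {}
    for col, typ in zip(table.X.columns, table.types):
        series = table.X[col].dropna()
        if series.empty:
            raise ValueError(f"column {col!r} is fully missing; drop it first")
        if typ == NUMERIC:
            fill[col] = float(series.mean())
        else:
            # deterministic mode: smallest level code on ties
            fill[col] = float(series.mode().min())
    return ImputationParams(fill)


def apply_imputer(table: LabeledTable, params: ImputationParams) -> LabeledTable:
    out = table.copy()
    out.X = out.X.fillna(pd.Series(params.fill))
    return out


def impute(table: LabeledTable) -> LabeledTable:
    """Mean/mode imputation fitted on and applied to ``table``."""
    return apply_imputer(table, fit_imputer(table))


# ----------------------------------------------------------------------
# min-max normalization
# ----------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-numeric-column (min, max) on the original scale."""

    bounds: dict

    def __post_init__(self):
        for col, (lo, hi) in self.bounds.items():
            if hi < lo:
                raise ValueError(f"max < min for column {col!r}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.bounds, indent=2))

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        raw = json.loads(Path(path).read_text())
        return cls({k: (float(v[0]), float(v[1])) for k, v in raw.items()})


def fit_normalizer(table: LabeledTable) -> NormalizationParams:
    bounds = {}
    for col in table.numeric_columns():
        series = table.X[col]
        if series.isna().any():
            raise ValueError(f"numeric column {col!r} has missing cells; impute first")
        bounds[col] = (float(series.min()), float(series.max()))
    return NormalizationParams(bounds)


def apply_normalizer(table: LabeledTable, params: NormalizationParams) -> LabeledTable:
    out = table.copy()
    for col, (lo, hi) in params.bounds.items():
        if col not in out.X.columns:
            continue
        if hi == lo:
            # degenerate column: defined as 0 to keep the range contract
            out.X[col] = 0.0
        else:
            out.X[col] = (out.X[col] - lo) / (hi - lo)
    return out


def min_max_normalize(table: LabeledTable):
    """Rescale numeric columns to [0, 1]; returns (table, fitted params)."""
    params = fit_normalizer(table)
    return apply_normalizer(table, params), params


# ----------------------------------------------------------------------
# Epworth daytime-sleepiness bands
# ----------------------------------------------------------------------

def epworth_category(score: int) -> str:
    """Band label for an Epworth score in 0..24."""
    if not 0 <= score <= 24:
        raise ValueError(f"Epworth score must lie in [0, 24], got {score}")
    for lo, hi, label in EPWORTH_BANDS:
        if lo <= score <= hi:
            return label
    raise AssertionError("unreachable")


# ----------------------------------------------------------------------
# demographic grouping
# ----------------------------------------------------------------------

_DEFAULT_ROLE_COLUMNS = {"race": "Race", "sex": "Sex", "age": "Age"}


@dataclass
class GroupSpec:
    """How to split a table into demographic groups.

    For race and sex the grouping column is removed from each output
    (its value is constant within a group); for age it is retained.
    """

    group_variable: str
    age_threshold: float = 50.0
    column: str = None
    drop_group_column: bool = None

    def __post_init__(self):
        if self.group_variable not in ("race", "sex", "age"):
            raise ValueError(f"unknown group variable {self.group_variable!r}")
        if self.column is None:
            self.column = _DEFAULT_ROLE_COLUMNS[self.group_variable]
        if self.drop_group_column is None:
            self.drop_group_column = self.group_variable != "age"


def split_groups(table: LabeledTable, spec: GroupSpec) -> dict:
    """Partition rows by the spec's demographic variable.

    Returns ``{group label: LabeledTable}``.  Age groups are
    ``le<threshold>`` (inclusive) and ``gt<threshold>``.
    """
    col = spec.column
    if col not in table.X.columns:
        raise ValueError(f"group column {col!r} not present in table")
    values = table.X[col]
    if values.isna().any():
        raise ValueError(f"group column {col!r} has missing values; impute first")

    if spec.group_variable == "age":
        t = spec.age_threshold
        assignments = np.where(values.to_numpy() <= t, f"le{t:g}", f"gt{t:g}")
    else:
        codes = values.to_numpy().astype(int)
        levels = table.levels.get(col)
        if levels is not None:
            assignments = np.asarray([str(levels[c]) for c in codes])
        else:
            assignments = np.asarray([str(c) for c in codes])

    groups = {}
    for label in pd.unique(assignments):
        rows = np.flatnonzero(assignments == label)
        sub = table.select_rows(rows)
        if spec.drop_group_column:
            sub = sub.drop_column(col)
        groups[label] = sub
    return groups


# ----------------------------------------------------------------------
# default pipeline
# ----------------------------------------------------------------------

def preprocess(table: LabeledTable, sparse_threshold: float = 0.5):
    """drop_sparse -> impute -> min-max normalize.

    Fitted on the full table, mirroring a preprocessing-before-CV
    protocol; use :func:`osadx.evaluation.cross_validate` with
    ``fit_preprocess_per_fold=True`` for a leakage-free variant.
    Returns (clean table, NormalizationParams).
    """
    out = drop_sparse(table, sparse_threshold)
    out = impute(out)
    return min_max_normalize(out)
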