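"""Confusion-matrix metrics, mean-rank comparison, and paired tests.

The metric suite follows the evaluation convention of the study this
package reproduces: "AUC" denotes balanced accuracy (TPR+TNR)/2, not a
ROC integral.  A true ROC area is available separately as
:func:`roc_auc`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "confusion_metrics",
    "balanced_auc",
    "g_mean",
    "f_score",
    "roc_auc",
    "mean_rank",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
]

METRIC_FIELDS = (
    "accuracy", "tpr", "tnr", "auc", "precision", "f_score", "g_mean",
)


@dataclass(frozen=True)
class MetricsReport:
    """Eight-field summary of a binary confusion matrix.

    ``undefined`` lists metric names whose denominator was zero; those
    metrics are reported as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    tpr: float
    tnr: float
    auc: float
    precision: float
    f_score: float
    g_mean: float
    undefined: tuple = field(default=())

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("tp", "fp", "tn", "fn")}
        d.update({k: getattr(self, k) for k in METRIC_FIELDS})
        return d


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def confusion_metrics(tp: int, fp: int, tn: int, fn: int,
                      swap_classes: bool = False) -> MetricsReport:
    """Compute the metric suite from raw confusion counts.

    ``swap_classes=True`` exchanges the roles of the two classes
    (tp<->tn, fp<->fn) before computing, for datasets whose reported
    rates were taken with the opposite positive-class convention.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError(f"confusion counts must be non-negative, got {counts}")
    if sum(counts) == 0:
        raise ValueError("confusion counts sum to zero")
    if swap_classes:
        tp, fp, tn, fn = tn, fn, tp, fp

    undefined = []
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    tpr = _ratio(tp, tp + fn, "tpr", undefined)
    tnr = _ratio(tn, tn + fp, "tnr", undefined)
    precision = _ratio(tp, tp + fp, "precision", undefined)
    auc = balanced_auc(tpr, tnr)
    f = f_score(precision, tpr)
    if precision + tpr == 0:
        undefined.append("f_score")
    g = g_mean(tpr, tnr)
    return MetricsReport(
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        accuracy=accuracy, tpr=tpr, tnr=tnr, auc=auc,
        precision=precision, f_score=f, g_mean=g,
        undefined=tuple(undefined),
    )


def balanced_auc(tpr: float, tnr: float) -> float:
    """(TPR + TNR) / 2 — the tables' "AUC" column."""
    return (tpr + tnr) / 2.0


def g_mean(tpr: float, tnr: float) -> float:
    """Geometric mean of TPR and TNR."""
    return math.sqrt(tpr * tnr)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_auc(labels, scores) -> float:
    """Rank-based ROC area (the conventional AUC), provided separately."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def mean_rank(values, higher_is_better: bool = True) -> np.ndarray:
    """Friedman-style mean rank across criteria.

    ``values`` is a (methods x criteria) matrix.  Within each criterion
    column, methods are ranked 1 = best with average ranks on ties; the
    result is each method's mean rank across columns.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if np.isnan(values).any():
        raise ValueError("metric matrix must have no missing cells")
    cols = values if not higher_is_better else -values
    ranks = np.column_stack(
        [stats.rankdata(cols[:, j], method="average") for j in range(cols.shape[1])]
    )
    return ranks.mean(axis=1)


class WilcoxonResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded.  If all differences are zero the
    result is degenerate with p = 1.  The exact null distribution is
    used for n <= 15 when the absolute differences are tie-free;
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, True)
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 15 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), False)
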