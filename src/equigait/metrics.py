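"""Classification metrics, the Welch location comparison, and cohort summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .preprocessing import SUPERCLASSES

__all__ = [
    "confusion_matrix",
    "accuracy",
    "macro_f1",
    "WelchResult",
    "welch_test",
    "DatasetSummary",
    "dataset_summary",
]


def confusion_matrix(y_true, y_pred, labels=SUPERCLASSES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    return _sk_confusion_matrix(y_true, y_pred, labels=list(labels))


def _check_cm(cm) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty (zero total)")
    return cm


def accuracy(cm) -> float:
    """Overall accuracy in percent: trace / total × 100."""
    cm = _check_cm(cm)
    return float(np.trace(cm) / cm.sum() * 100.0)


def macro_f1(cm) -> float:
    """Unweighted mean of per-class F1 scores, in percent.

    Computed from first principles: per class, precision = tp / column sum,
    recall = tp / row sum, F1 their harmonic mean (0 when both are
    undefined or zero).  Classes absent from both truth and prediction are
    excluded from the mean.
    """
    cm = _check_cm(cm)
    f1s = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        row = cm[k].sum()
        col = cm[:, k].sum()
        if row == 0 and col == 0:
            continue
        prec = tp / col if col else 0.0
        rec = tp / row if row else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if (prec + rec) else 0.0)
    return float(np.mean(f1s) * 100.0)


class WelchResult(NamedTuple):
    t: float
    p: float
    significant: bool


def welch_test(sample_a, sample_b, alpha: float = 0.05) -> WelchResult:
    """Two-sided Welch t-test (unequal variances, Welch–Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if a.var() == 0 and b.var() == 0 and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0  # degenerate: identical constant samples
    return WelchResult(t=t, p=p, significant=bool(p < alpha))


@dataclass
class DatasetSummary:
    """Per-horse × per-gait sample bookkeeping.

    Percentages are reported rounded to 2 decimals; the underlying fractions
    are kept at full precision in ``counts`` / totals.
    """

    counts: pd.DataFrame
    gait_totals: pd.Series
    grand_total: int
    horse_pct_of_total: pd.Series
    horse_pct_of_gait: pd.DataFrame


def dataset_summary(counts: pd.DataFrame) -> DatasetSummary:
    """Summarise a horse × gait sample-count table.

    ``counts`` is indexed by horse with one column per gait.  Returns gait
    column totals, the grand total, each horse's percent share of all
    samples, and each horse's percent share of each gait's samples (2-decimal
    rounding throughout).
    """
    if counts.size == 0:
        raise ValueError("empty counts table")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    gait_totals = counts.sum(axis=0)
    grand_total = int(gait_totals.sum())
    if grand_total == 0:
        raise ValueError("counts table sums to zero")
    horse_pct = (counts.sum(axis=1) / grand_total * 100).round(2)
    gait_pct = (counts / gait_totals.replace(0, np.nan) * 100).round(2)
    return DatasetSummary(
        counts=counts,
        gait_totals=gait_totals,
        grand_total=grand_total,
        horse_pct_of_total=horse_pct,
        horse_pct_of_gait=gait_pct,
    )
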