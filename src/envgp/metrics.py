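"""Prediction-accuracy metric: Pearson correlation with an undefined flag."""

from __future__ import annotations

import numpy as np
from scipy import stats


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation between observed and predicted values.

    Returns NaN (flagged undefined) when either vector is constant —
    such folds are excluded from averages rather than counted as zero.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise ValueError("accuracy needs at least 2 observations")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        return float("nan")
    return float(stats.pearsonr(y_true, y_pred).statistic)
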