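"""Shared small statistics helpers: vectorized Pearson correlation with
t-test p-values, and Benjamini-Hochberg adjustment with input validation."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError


def pearson_matrix_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between every row of X (m x n) and the vector y (n,)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    return np.clip(r, -1.0, 1.0)


def pearson_matrix_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between every row of X (m x n) and every row of Y (k x n)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Yc.T) / np.outer(sx, sy)
    return np.clip(r, -1.0, 1.0)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-test p-value for a Pearson correlation, df = n - 2."""
    if n < 4:
        raise ValidationError(f"need >=4 samples for a correlation test, got {n}")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # |r| == 1 gives t = inf -> p = 0; r undefined (zero variance) -> p = nan
    return np.where(np.isnan(r), np.nan, np.clip(p, 0.0, 1.0))


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("adjust_bh expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1] with no NaN")
    return multipletests(p, method="fdr_bh")[1]
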