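"""Small shared statistical helpers.

These are thin, well-specified utilities used by several pipeline stages:
column z-scoring with sample (n-1) denominators, vectorized Pearson
correlation of many profiles against a common map, and Benjamini-Hochberg
adjustment that tolerates missing p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import NumericalError


def zscore_columns(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score every column of ``values`` across rows (sample SD by default).

    Raises :class:`NumericalError` naming the first zero-variance column.
    """
    sd = values.std(axis=0, ddof=ddof)
    zero = sd[~(sd > 0)]
    if len(zero):
        raise NumericalError(
            f"zero variance across regions for column {zero.index[0]!r}"
        )
    return (values - values.mean(axis=0)) / sd


def pearson_rows_vs_columns(rows: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` (n x p) with each column of ``columns`` (p x k).

    Returns an (n x k) matrix.  Rows with zero variance yield NaN.
    """
    rows = np.asarray(rows, dtype=float)
    columns = np.asarray(columns, dtype=float)
    rc = rows - rows.mean(axis=1, keepdims=True)
    cc = columns - columns.mean(axis=0, keepdims=True)
    rn = np.sqrt((rc**2).sum(axis=1, keepdims=True))
    cn = np.sqrt((cc**2).sum(axis=0, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (rc @ cc) / (rn * cn)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Plain Pearson correlation with two-sided p-value."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaN entries stay NaN."""
    arr = np.asarray(pvalues, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out
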