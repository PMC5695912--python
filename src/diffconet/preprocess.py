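"""Matrix preprocessing: quantile normalization and log2 transform."""

from __future__ import annotations

import warnings

import numpy as np


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column onto the common row-mean-of-sorted-values distribution.

    Ties within a column receive the mean of the target quantiles they span
    (the convention of limma's normalizeQuantiles). A single-column matrix is
    returned unchanged with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("quantile_normalize expects a 2-D matrix")
    n_rows, n_cols = x.shape
    if n_cols < 2:
        warnings.warn("quantile normalization of a single column is the identity")
        return x.copy()
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_cols):
        order = np.argsort(x[:, j], kind="mergesort")
        assigned = np.empty(n_rows)
        assigned[order] = target
        # tied cells all receive the mean of the target slots they occupy
        _, inverse = np.unique(x[:, j], return_inverse=True)
        group_mean = np.bincount(inverse, weights=assigned) / np.bincount(inverse)
        out[:, j] = group_mean[inverse]
    return out


def log2_transform(matrix: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Elementwise log2(value + offset); every argument must be positive."""
    x = np.asarray(matrix, dtype=float) + offset
    bad = ~(x > 0)
    if bad.any():
        cells = [tuple(int(v) for v in idx) for idx in np.argwhere(bad)[:5]]
        raise ValueError(f"log2 transform undefined at cells {cells} (value+offset <= 0)")
    return np.log2(x)
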