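"""Cross-sample quantile normalization.

Forces every sample (column) to share the common distribution of rank-wise
means: sort each column, average across columns at each rank, and map each
value back to the mean at its rank.  Ties within a column all receive the
mean of the rank means over their tied span, so the column sum (and the
grand mean) is preserved and the transform is idempotent.

Applied to linear-scale values before any log transform.
"""

from __future__ import annotations

import warnings

import numpy as np

from .expression_io import ExpressionMatrix

__all__ = ["quantile_normalize"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize a gene-by-sample matrix across samples.

    A single-sample matrix is returned unchanged with a warning.
    """
    X = matrix.values
    n_genes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn(
            "quantile normalization needs at least 2 samples; returning input unchanged",
            stacklevel=2,
        )
        return matrix.with_values(X)

    order = np.argsort(X, axis=0, kind="stable")
    sorted_X = np.take_along_axis(X, order, axis=0)
    rank_means = sorted_X.mean(axis=1)

    out = np.empty_like(X, dtype=float)
    rows = np.arange(n_genes)
    for j in range(n_samples):
        col_out = np.empty(n_genes, dtype=float)
        col_out[order[:, j]] = rank_means
        # ties: every member of a tied block gets the block mean
        uniq, inverse, counts = np.unique(
            X[:, j], return_inverse=True, return_counts=True
        )
        if len(uniq) < n_genes:
            sums = np.bincount(inverse, weights=col_out)
            col_out = (sums / counts)[inverse]
        out[rows, j] = col_out
    return matrix.with_values(out)
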