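"""Small shared statistical helpers (PCA on a correlation matrix, BH-FDR)."""
from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["pca_correlation", "fdr_bh"]


def pca_correlation(data: np.ndarray | None = None, corr: np.ndarray | None = None):
    """Principal components of a set of variables via their correlation matrix.

    Standardising each column and eigendecomposing the correlation matrix puts
    variables with different variances on an equal footing; the eigenvalues sum
    to the number of variables k, so each eigenvalue divided by k is the
    fraction of (standardised) variance explained.

    Parameters
    ----------
    data : array (n_observations, k), optional
        Raw variable columns. Required when scores are wanted.
    corr : array (k, k), optional
        Correlation matrix; computed from ``data`` when omitted.

    Returns
    -------
    fractions : array (k,)
        Variance fractions per component, descending; sums to 1.
    scores : array (n_observations, k) or None
        Component scores of the standardised data (None without ``data``).
    loadings : array (k, k)
        Eigenvectors in columns, matching ``fractions`` order.
    """
    if corr is None:
        if data is None:
            raise ValueError("provide data or corr")
        data = np.asarray(data, dtype=float)
        if np.any(np.std(data, axis=0) == 0):
            raise ValueError("zero-variance column")
        corr = np.corrcoef(data, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # deterministic sign: dominant loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    fractions = eigval / k
    scores = None
    if data is not None:
        z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
        scores = z @ eigvec
    return fractions, scores, eigvec


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
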