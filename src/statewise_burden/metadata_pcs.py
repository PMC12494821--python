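"""Sequencing-metadata principal components.

PCs of per-sample sequencing QC metrics (mean depth, contamination,
coverage completeness, ...) serve as batch-effect covariates: when two
cohorts were sequenced at different depths, the leading metadata PCs track
depth and absorb depth-driven differential variant calling in burden tests.
The first four PCs are used by default, mirroring the point at which the
cumulative variance explained saturates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["metric_matrix", "compute_metadata_pcs"]


def metric_matrix(samples: list) -> pd.DataFrame:
    """samples x metrics DataFrame (index = sample_id)."""
    rows = {s.sample_id: s.metrics for s in samples}
    return pd.DataFrame.from_dict(rows, orient="index")


def compute_metadata_pcs(metrics: pd.DataFrame, k: int = 4):
    """PCA of z-standardised QC metrics.

    Missing values are imputed with the column median before
    standardisation; constant columns are dropped with a warning.  The sign
    of each component is fixed by its largest-magnitude metric loading.
    Returns ``(scores, variance_explained)`` with ``scores`` of shape
    (n_samples, k) and per-component variance-explained fractions.
    """
    X = metrics.to_numpy(dtype=float).copy()
    names = list(metrics.columns)
    # median imputation
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            col[bad] = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
            X[:, j] = col
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping constant metric columns: {[names[j] for j in np.flatnonzero(const)]}")
        X = X[:, ~const]
        sd = sd[~const]
    if X.shape[1] < k:
        raise ValueError(f"need >= {k} non-constant metrics, have {X.shape[1]}")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for c in range(Vt.shape[0]):
        jmax = np.argmax(np.abs(Vt[c]))
        if Vt[c, jmax] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    scores = (U * s)[:, :k]
    var_explained = (s**2) / (s**2).sum()
    return scores, var_explained[:k]
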