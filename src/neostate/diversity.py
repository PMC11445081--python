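"""Alpha diversity and the Jensen-Shannon divergence matrix.

Everything is in natural-log units (nats): Shannon diversity lies in
[0, ln S] and the Jensen-Shannon divergence (JSD) between two compositions in
[0, ln 2]. Community typing downstream clusters the raw JSD matrix by
default; the square root of JSD is a metric, so a ``sqrt`` variant is exposed
for ordinations that need one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .tables import AbundanceTable

__all__ = ["shannon_diversity", "shannon_diversity_table", "jsd_matrix"]


def shannon_diversity(p) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) of one abundance vector."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("abundances must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon_diversity_table(table: AbundanceTable) -> pd.Series:
    """Per-sample Shannon diversity of an abundance table."""
    return pd.Series(
        [shannon_diversity(row) for row in table.values],
        index=table.data.index,
        name="shannon",
    )


def jsd_matrix(table: AbundanceTable, sqrt: bool = False) -> DistanceMatrix:
    """All-pairs Jensen-Shannon divergence of the rows of ``table``.

    JSD(P, Q) = H(M) - (H(P) + H(Q)) / 2 with M = (P + Q) / 2, natural log and
    the convention 0 ln 0 = 0. No pseudocount is needed: M is positive
    wherever P or Q is. With ``sqrt=True`` the square root (a true metric) is
    returned instead.
    """
    X = table.values
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(X > 0, X * np.log(X), 0.0)
    h = -plogp.sum(axis=1)  # per-sample entropies
    D = np.zeros((n, n))
    for i in range(n):
        M = 0.5 * (X[i] + X[i + 1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            hm = -np.where(M > 0, M * np.log(M), 0.0).sum(axis=1)
        d = hm - 0.5 * (h[i] + h[i + 1:])
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    np.clip(D, 0.0, np.log(2), out=D)  # guard tiny negative rounding
    np.fill_diagonal(D, 0.0)
    if sqrt:
        D = np.sqrt(D)
    return DistanceMatrix(D, ids=table.sample_ids)
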