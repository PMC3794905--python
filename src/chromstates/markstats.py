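"""Rank transform, Spearman correlation structure and mark ordering.

Mark densities are heavy-tailed, so all correlation analysis runs on
column-wise ranks (ties take the maximum rank of their tied block, matching
R's ``rank(ties.method = "max")``).  The Spearman correlation matrix is the
Pearson correlation of the rank columns; marks are ordered for display by
average-linkage hierarchical clustering of the correlation distance
``d = 1 - rho``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

log = logging.getLogger(__name__)


def rank_transform(matrix: np.ndarray) -> np.ndarray:
    """Column-wise ranks 1..n with ties assigned the maximum tied rank."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot rank an empty matrix")
    if np.isnan(matrix).any():
        raise ValueError("rank transform requires complete data; drop invalid windows first")
    return rankdata(matrix, method="max", axis=0).astype(np.int64)


def spearman_matrix(rank_matrix: np.ndarray) -> np.ndarray:
    """Pearson correlation of rank columns (= Spearman of the raw data).

    Zero-variance columns yield NaN rows/columns, reported via a warning.
    """
    R = np.asarray(rank_matrix, dtype=float)
    if R.shape[0] < 3:
        raise ValueError("need at least 3 windows to correlate")
    sd = R.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(R, rowvar=False)
    rho = np.atleast_2d(rho)
    if degenerate.size:
        log.warning("zero-variance columns with undefined correlations: %s", degenerate)
        rho[degenerate, :] = np.nan
        rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def mark_mrt_correlation(rank_matrix: np.ndarray, mrt: np.ndarray) -> np.ndarray:
    """Spearman correlation of every mark with mean replication timing."""
    R = np.asarray(rank_matrix, dtype=float)
    r_mrt = rankdata(mrt, method="max").astype(float)
    full = np.column_stack([R, r_mrt])
    return spearman_matrix(full)[:-1, -1]


def correlation_distance(rho: np.ndarray) -> np.ndarray:
    """Correlation distance ``d = 1 - rho`` (0 for perfectly correlated marks)."""
    rho = np.asarray(rho, dtype=float)
    if np.nanmax(np.abs(rho)) > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage_order(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative average-linkage clustering of a distance matrix.

    Returns ``(leaf_order, merge_tree)`` where ``merge_tree`` is a scipy
    linkage matrix and ``leaf_order`` places merged pairs adjacently.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] == 1:
        return np.array([0]), np.zeros((0, 4))
    Z = linkage(squareform(d, checks=False), method="average")
    return np.asarray(leaves_list(Z)), Z
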