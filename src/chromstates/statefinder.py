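"""Chromatin-state discovery: PCA, CLARA k-medoids, diagnostics, labeling.

The segmentation pipeline is: column-standardized PCA of the rank-transformed
windows x marks matrix (first 3 components retained), CLARA k-medoids
clustering in that 3-D score space, cluster-number diagnostics (pooled
within-cluster sum of squares and the gap statistic against a uniform
reference), removal of windows with negative silhouette (borderline
allocations, demoted to the unclassified state D), and naming of the
surviving clusters as chromatin states C1-C4 from the mean ranks of
signature marks.

CLARA (Clustering LARge Applications) runs PAM (k-medoids with BUILD + SWAP
phases, Euclidean metric) on repeated random subsamples and keeps the medoid
set with the lowest total assignment cost over all points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .reference import DEFAULT_MARK_ROLES

log = logging.getLogger(__name__)

UNCLASSIFIED = "D"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    loadings: np.ndarray          # marks x all components (columns orthonormal)
    variance_fractions: np.ndarray
    scores: np.ndarray            # windows x retained components
    n_retained: int


def fit_pca(rank_matrix: np.ndarray, n_retained: int = 3) -> PcaModel:
    """PCA of the column-centered, unit-variance rank matrix.

    Components are ordered by decreasing eigenvalue; scores are returned for
    the first ``n_retained`` components (3 by default).
    """
    X = np.asarray(rank_matrix, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more windows than marks for a stable PCA")
    sd = X.std(axis=0)
    degenerate = sd <= 1e-10 * (1.0 + np.abs(X.mean(axis=0)))
    if np.any(degenerate):
        raise ValueError(f"constant mark column(s) at index {np.flatnonzero(degenerate)}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=X.shape[1], svd_solver="full")
    scores = pca.fit_transform(Z)
    return PcaModel(
        loadings=pca.components_.T,
        variance_fractions=pca.explained_variance_ratio_,
        scores=scores[:, :n_retained],
        n_retained=n_retained,
    )


# ---------------------------------------------------------------------------
# PAM / CLARA
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    k: int
    medoids: np.ndarray           # k x dim coordinates (data points)
    medoid_indices: np.ndarray    # indices into the clustered data
    assignment: np.ndarray        # per-point cluster index in 0..k-1
    total_cost: float


def pam(D: np.ndarray, k: int, max_iter: int = 300) -> np.ndarray:
    """k-medoids on a full distance matrix: greedy BUILD then best-swap SWAP.

    Returns the sorted medoid indices.  Deterministic: ties break on the
    lowest index.
    """
    n = D.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} points")
    # BUILD: first medoid minimizes total distance, then greedy max gain
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gain = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    med = np.array(sorted(medoids))
    # SWAP: repeatedly apply the single best cost-decreasing (medoid, point) swap
    for _ in range(max_iter):
        dm = D[:, med]
        order = np.argsort(dm, axis=1, kind="stable")
        idx = np.arange(n)
        d1 = dm[idx, order[:, 0]]
        d2 = dm[idx, order[:, 1]] if k > 1 else np.full(n, np.inf)
        n1 = order[:, 0]
        best_delta, best_swap = -1e-10, None
        for mi in range(k):
            own = n1 == mi
            # candidate h replaces med[mi]; cost change summed over points
            delta = np.minimum(d2[own, None], D[own, :]).sum(axis=0) - d1[own].sum()
            delta += np.minimum(D[~own, :] - d1[~own, None], 0.0).sum(axis=0)
            delta[med] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        med[best_swap[0]] = best_swap[1]
        med = np.sort(med)
    return med


def _assign(points: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    d = cdist(points, medoids)
    a = np.argmin(d, axis=1)
    return a, float(d[np.arange(len(points)), a].sum())


def clara(
    points: np.ndarray,
    k: int,
    sample_size: int = 500,
    n_samples: int = 20,
    seed: int | np.random.Generator = 0,
) -> ClusterModel:
    """CLARA k-medoids: PAM on random subsamples, best solution over all points.

    With ``sample_size >= n`` this reduces exactly to PAM on the full data.
    Features are expected to be scaled upstream; no internal standardization.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if k > len(np.unique(points, axis=0)):
        raise ValueError(f"k={k} exceeds the number of distinct points")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n <= sample_size:
        med_idx = pam(cdist(points, points), k)
        assignment, cost = _assign(points, points[med_idx])
        return ClusterModel(k, points[med_idx], med_idx, assignment, cost)
    best: ClusterModel | None = None
    for _ in range(n_samples):
        sub = np.sort(rng.choice(n, size=sample_size, replace=False))
        spts = points[sub]
        med_local = pam(cdist(spts, spts), k)
        med_idx = sub[med_local]
        assignment, cost = _assign(points, points[med_idx])
        if best is None or cost < best.total_cost:
            best = ClusterModel(k, points[med_idx], med_idx, assignment, cost)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# cluster-number diagnostics
# ---------------------------------------------------------------------------


def wss(points: np.ndarray, assignment: np.ndarray) -> tuple[float, np.ndarray]:
    """Pooled within-cluster sum of squared distances to the cluster mean.

    Returns ``(W_k, per_cluster)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.unique(assignment)
    per = np.empty(len(labels))
    for i, lab in enumerate(labels):
        sub = points[assignment == lab]
        per[i] = ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(per.sum()), per


@dataclass
class GapResult:
    ks: np.ndarray
    log_w_data: np.ndarray
    gap: np.ndarray
    se: np.ndarray          # Monte-Carlo standard error, Tibshirani's s_k


def gap_statistic(
    points: np.ndarray,
    ks: list[int],
    B: int = 50,
    seed: int | np.random.Generator = 0,
    **clara_kwargs,
) -> GapResult:
    """Gap(k) = E_ref[log W_k] - log W_k with a uniform reference distribution.

    The reference datasets are drawn uniformly over the per-dimension range of
    the observed data and clustered with the same CLARA procedure.
    """
    if B < 2:
        raise ValueError("need B >= 2 reference datasets")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = points.min(axis=0), points.max(axis=0)
    refs = [rng.uniform(lo, hi, size=points.shape) for _ in range(B)]
    log_w_data = np.empty(len(ks))
    gap = np.empty(len(ks))
    se = np.empty(len(ks))
    for i, k in enumerate(ks):
        log_w_data[i] = np.log(_wk(points, k, rng, clara_kwargs))
        log_w_ref = np.array([np.log(_wk(r, k, rng, clara_kwargs)) for r in refs])
        gap[i] = log_w_ref.mean() - log_w_data[i]
        se[i] = log_w_ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return GapResult(np.array(ks), log_w_data, gap, se)


def _wk(points: np.ndarray, k: int, rng: np.random.Generator, clara_kwargs: dict) -> float:
    if k == 1:
        return max(wss(points, np.zeros(len(points), dtype=int))[0], 1e-300)
    model = clara(points, k, seed=rng, **clara_kwargs)
    return max(wss(points, model.assignment)[0], 1e-300)


def select_k_elbow(ks: np.ndarray, wss_by_k: np.ndarray) -> int:
    """Elbow heuristic: k maximizing the second difference of log W_k.

    The crossover from fast to weak decrease of the pooled within-cluster sum
    of squares is a change in *relative* slope, so the second difference is
    taken on the log scale (the raw scale is dominated by the first split).
    """
    ks = np.asarray(ks)
    w = np.log(np.asarray(wss_by_k, dtype=float))
    if len(ks) < 3:
        raise ValueError("need at least 3 k values for a second difference")
    second = w[:-2] - 2 * w[1:-1] + w[2:]
    return int(ks[1:-1][np.argmax(second)])


def select_k_gap(result: GapResult) -> int:
    """Smallest k with Gap(k) >= Gap(k+1) - se(k+1) (the one-SE rule)."""
    g, s, ks = result.gap, result.se, result.ks
    for i in range(len(ks) - 1):
        if g[i] >= g[i + 1] - s[i + 1]:
            return int(ks[i])
    return int(ks[-1])


# ---------------------------------------------------------------------------
# silhouettes and filtering
# ---------------------------------------------------------------------------


def silhouettes(
    points: np.ndarray, assignment: np.ndarray, chunk: int = 2048
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point silhouette ingredients ``(a, b, s)``.

    ``a(i)`` is the mean distance to the other members of i's cluster,
    ``b(i)`` the smallest mean distance to another cluster, and
    ``s = (b - a) / max(a, b)``.  Points in singleton clusters get s = 0.
    Computed in row chunks so memory stays O(chunk * n).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if len(labels) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(points)
    sizes = np.array([(assignment == lab).sum() for lab in labels])
    # M[i, j] = mean distance from point i to members of cluster j
    M = np.empty((n, len(labels)))
    members = [points[assignment == lab] for lab in labels]
    for s0 in range(0, n, chunk):
        sl = slice(s0, min(s0 + chunk, n))
        for j, mem in enumerate(members):
            M[sl, j] = cdist(points[sl], mem).mean(axis=1)
    own = np.searchsorted(labels, assignment)
    own_size = sizes[own]
    # exclude self from the own-cluster mean
    a = np.where(own_size > 1, M[np.arange(n), own] * own_size / np.maximum(own_size - 1, 1), 0.0)
    Mb = M.copy()
    Mb[np.arange(n), own] = np.inf
    b = Mb.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[own_size == 1] = 0.0
    return a, b, s


def filter_unclassified(assignment: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, int]:
    """Demote points with negative silhouette to the unclassified label (-1).

    These are borderline allocations: closer on average to another cluster
    than to their own.  Returns the filtered assignment and the count demoted.
    """
    filtered = np.asarray(assignment).copy()
    bad = np.asarray(s) < 0
    filtered[bad] = -1
    return filtered, int(bad.sum())


# ---------------------------------------------------------------------------
# labeling clusters as chromatin states
# ---------------------------------------------------------------------------


@dataclass
class StateAssignment:
    labels: np.ndarray            # per-window state name in {C1..C4, D}
    label_map: dict[int, str]     # cluster index -> state name
    silhouette: np.ndarray | None = None
    filtered_count: int = 0
    diagnostics: dict = field(default_factory=dict)


def label_states(
    assignment: np.ndarray,
    rank_matrix: np.ndarray,
    mark_names: list[str],
    mark_roles: dict[str, tuple[str, ...]] | None = None,
) -> StateAssignment:
    """Name clusters C1-C4 from the mean ranks of signature marks.

    C1 is the cluster with the highest mean rank over active marks; among the
    remainder C4 has the highest HP1-signature rank, then C2 the highest
    Polycomb rank, and C3 is the residual cluster.  With exactly two clusters
    the naming degrades to an active/silent dichotomy.  ``assignment`` may
    contain -1 for already-unclassified points.
    """
    roles = dict(DEFAULT_MARK_ROLES if mark_roles is None else mark_roles)
    name_to_col = {m: i for i, m in enumerate(mark_names)}
    for role, marks in roles.items():
        missing = [m for m in marks if m not in name_to_col]
        if missing:
            raise ValueError(f"role {role!r} names marks absent from the matrix: {missing}")
    assignment = np.asarray(assignment)
    clusters = sorted(int(c) for c in np.unique(assignment) if c >= 0)
    R = np.asarray(rank_matrix, dtype=float)

    def role_score(cluster: int, role: str) -> float:
        cols = [name_to_col[m] for m in roles[role]]
        return float(R[np.ix_(assignment == cluster, cols)].mean())

    def argmax_role(cands: list[int], role: str) -> int:
        scores = [role_score(c, role) for c in cands]
        top = max(scores)
        ties = [c for c, sc in zip(cands, scores) if abs(sc - top) <= 1e-12]
        if len(ties) > 1:
            log.warning("clusters %s tie on role %r; keeping lowest index", ties, role)
        return min(ties)

    label_map: dict[int, str] = {}
    remaining = list(clusters)
    if len(clusters) == 2:
        c_active = argmax_role(remaining, "active")
        label_map[c_active] = "active"
        label_map[next(c for c in remaining if c != c_active)] = "silent"
    else:
        c1 = argmax_role(remaining, "active")
        label_map[c1] = "C1"
        remaining.remove(c1)
        c4 = argmax_role(remaining, "hp1")
        label_map[c4] = "C4"
        remaining.remove(c4)
        c2 = argmax_role(remaining, "polycomb")
        label_map[c2] = "C2"
        remaining.remove(c2)
        for i, c in enumerate(remaining):
            label_map[c] = "C3" if i == 0 else f"C{5 + i}"
    labels = np.array(
        [label_map.get(int(c), UNCLASSIFIED) for c in assignment], dtype=object
    )
    return StateAssignment(labels=labels, label_map=label_map)


# ---------------------------------------------------------------------------
# end-to-end segmentation
# ---------------------------------------------------------------------------


def segment(
    mark_matrix: np.ndarray,
    mark_names: list[str],
    k: int = 4,
    n_components: int = 3,
    sample_size: int = 500,
    n_samples: int = 20,
    seed: int = 0,
    mark_roles: dict[str, tuple[str, ...]] | None = None,
) -> StateAssignment:
    """Full pipeline: rank -> PCA -> CLARA -> silhouette filter -> label."""
    from .markstats import rank_transform

    ranks = rank_transform(mark_matrix)
    model = fit_pca(ranks, n_retained=n_components)
    cm = clara(model.scores, k, sample_size=sample_size, n_samples=n_samples, seed=seed)
    a, b, s = silhouettes(model.scores, cm.assignment)
    filtered, n_removed = filter_unclassified(cm.assignment, s)
    sa = label_states(filtered, ranks, mark_names, mark_roles)
    sa.silhouette = s
    sa.filtered_count = n_removed
    sa.diagnostics = {"pca": model, "clusters": cm, "a": a, "b": b}
    return sa
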