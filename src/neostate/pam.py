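"""Partitioning around medoids (PAM) on a divergence matrix.

The clustering route of community typing: k-medoids on the all-pairs
Jensen-Shannon divergence, with the number of clusters chosen by the
Calinski-Harabasz (CH) index and validated by mean silhouette width.

The implementation is the classical BUILD + SWAP algorithm: BUILD greedily
seeds medoids, SWAP repeatedly applies the best strictly-improving (medoid,
non-medoid) exchange, and ties break to the lowest sample index. Because a
single BUILD start can end in a SWAP local minimum even on small instances,
a few additional seeded random starts are run and the lowest-cost local
minimum is kept; the result is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_samples

from .assignments import StateAssignment

__all__ = [
    "pam_cluster",
    "calinski_harabasz",
    "silhouette_width",
    "select_k_pam",
    "ClusterQuality",
]


@dataclass
class ClusterQuality:
    k: int
    ch_index: float
    mean_silhouette: float


def _as_array(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.data
    A = np.asarray(D, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return A


def _ids(D, n) -> list:
    if isinstance(D, DistanceMatrix):
        return list(D.ids)
    return [str(i) for i in range(n)]


def _assign_to_medoids(A: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # ties go to the medoid listed first; medoids are kept sorted by index
    return medoids[np.argmin(A[:, medoids], axis=1)]


def _build_phase(A: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD: each new medoid minimizes the summed nearest distance."""
    totals = A.sum(axis=0)
    medoids = [int(np.argmin(totals))]
    nearest = A[:, medoids[0]].copy()
    while len(medoids) < k:
        cand_cost = np.minimum(nearest[:, None], A).sum(axis=0)
        cand_cost[medoids] = np.inf
        m = int(np.argmin(cand_cost))
        medoids.append(m)
        nearest = np.minimum(nearest, A[:, m])
    return np.array(sorted(medoids))


def _swap_phase(A: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Best strictly-improving exchanges until a local minimum is reached."""
    n = A.shape[0]
    k = medoids.size
    cost = float(A[np.arange(n), _assign_to_medoids(A, medoids)].sum())
    while True:
        dist_to_medoids = A[:, medoids]  # (n, k)
        order = np.argsort(dist_to_medoids, axis=1)
        d1 = dist_to_medoids[np.arange(n), order[:, 0]]
        if k > 1:
            d2 = dist_to_medoids[np.arange(n), order[:, 1]]
        else:
            d2 = np.full(n, np.inf)
        nearest_idx = order[:, 0]

        best = (0.0, None)  # (delta, (position, candidate))
        for pos in range(k):
            # distance to nearest medoid excluding the one being removed
            excl = np.where(nearest_idx == pos, d2, d1)
            new_costs = np.minimum(excl[:, None], A).sum(axis=0)
            new_costs[medoids] = np.inf
            h = int(np.argmin(new_costs))
            delta = new_costs[h] - cost
            if delta < best[0] - 1e-12:
                best = (delta, (pos, h))
        if best[1] is None:
            break
        pos, h = best[1]
        new_medoids = medoids.copy()
        new_medoids[pos] = h
        new_medoids = np.sort(new_medoids)
        new_cost = float(A[np.arange(n), _assign_to_medoids(A, new_medoids)].sum())
        assert new_cost <= cost + 1e-9, "PAM cost increased during SWAP"
        medoids, cost = new_medoids, new_cost
    return medoids, cost


def pam_cluster(D, k: int, seed: int = 0, n_starts: int = 5) -> StateAssignment:
    """Cluster a distance matrix into ``k`` groups around medoids.

    The first start uses the deterministic greedy BUILD initialization; the
    remaining ``n_starts - 1`` starts use seeded random medoid sets, and the
    lowest-cost SWAP local minimum wins (ties prefer the BUILD start). The
    result is deterministic given ``D``, ``k`` and ``seed``. The total cost
    is asserted non-increasing within every SWAP phase.
    """
    A = _as_array(D)
    n = A.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    ids = _ids(D, n)

    rng = np.random.default_rng(seed)
    medoids, cost = _swap_phase(A, _build_phase(A, k))
    for _ in range(max(0, n_starts - 1)):
        init = np.sort(rng.choice(n, size=k, replace=False))
        cand_medoids, cand_cost = _swap_phase(A, init)
        if cand_cost < cost - 1e-12:
            medoids, cost = cand_medoids, cand_cost

    assigned = _assign_to_medoids(A, medoids)
    medoid_to_cluster = {m: f"C{j}" for j, m in enumerate(medoids)}
    labels = [medoid_to_cluster[m] for m in assigned]
    return StateAssignment(
        sample_ids=ids,
        labels=labels,
        method="PAM",
        k=k,
        medoid_ids=[ids[m] for m in medoids],
        state_names={},
    )


def calinski_harabasz(D, labels) -> float:
    """Distance-based Calinski-Harabasz index.

    Within-cluster dispersion is computed directly from pairwise squared
    distances via W = sum_c (1/n_c) sum_{i<j in c} d_ij^2 and total dispersion
    T = (1/n) sum_{i<j} d_ij^2, so no embedding of the divergence matrix is
    needed. Returns +inf when W = 0 (duplicated points per cluster).
    """
    A = _as_array(D)
    labels = np.asarray(list(labels))
    n = A.shape[0]
    if labels.shape[0] != n:
        raise ValueError("one label per sample required")
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least 2 clusters")
    sq = A ** 2
    T = sq.sum() / 2.0 / n
    W = 0.0
    for lab in uniq:
        idx = np.where(labels == lab)[0]
        if idx.size == 0:
            raise ValueError("empty cluster")
        W += sq[np.ix_(idx, idx)].sum() / 2.0 / idx.size
    B = T - W
    if W <= 0:
        return float("inf")
    return float((B / (k - 1)) / (W / (n - k)))


def silhouette_width(D, labels) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths and their mean (singletons score 0)."""
    A = _as_array(D)
    labels = np.asarray(list(labels))
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 clusters")
    widths = silhouette_samples(A, labels, metric="precomputed")
    return widths, float(widths.mean())


def select_k_pam(D, k_range, seed: int = 0):
    """PAM over a range of k; the chosen k maximizes the CH index.

    Returns ``(chosen_k, quality, assignments)`` where ``quality`` is a
    DataFrame of per-k CH and mean silhouette and ``assignments`` maps k to
    its :class:`StateAssignment`. Ties on CH break to the smaller k.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k range")
    n = _as_array(D).shape[0]
    if k_range[0] < 2 or k_range[-1] >= n:
        raise ValueError("k range must lie within [2, n-1]")
    rows, assignments = [], {}
    for k in k_range:
        assignment = pam_cluster(D, k, seed=seed)
        ch = calinski_harabasz(D, assignment.labels)
        _, mean_sil = silhouette_width(D, assignment.labels)
        rows.append(ClusterQuality(k=k, ch_index=ch, mean_silhouette=mean_sil))
        assignments[k] = assignment
    quality = pd.DataFrame([vars(q) for q in rows]).set_index("k")
    chosen = int(quality["ch_index"].idxmax())
    return chosen, quality, assignments
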