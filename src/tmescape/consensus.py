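"""Consensus clustering of cell-fraction profiles with CDF-based choice of k.

For each candidate k, samples are repeatedly subsampled (fraction
``p_item``) and clustered (K-means or PAM); the consensus matrix entry
(i, j) is the proportion of co-sampled iterations in which i and j fell
in the same cluster. The empirical CDF of consensus values across k
drives the selection of the number of TME subtypes: we take the
smallest k for which allowing one more cluster increases the area under
the consensus CDF by less than a relative threshold (default 10%).
Final labels come from average-linkage hierarchical clustering of
1 - consensus at the chosen k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

CDF_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, CDF summaries and the final partition.

    ``resample_log[k]`` records every resampling iteration as a pair
    ``(indices, labels)`` so that any consensus entry can be re-tallied
    from first principles.
    """

    k_range: list[int]
    consensus: dict[int, np.ndarray]
    cdf: dict[int, np.ndarray]
    area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    labels: np.ndarray
    method: str
    reps: int
    p_item: float
    resample_log: dict[int, list[tuple[np.ndarray, np.ndarray]]] = field(repr=False, default_factory=dict)


def _pam(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50) -> np.ndarray:
    """Partitioning around medoids: greedy BUILD then SWAP to convergence.

    Ties in total within-cluster cost break toward the lower cost (first
    improving swap wins per pass).
    """
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    # BUILD: first medoid minimizes total distance; rest maximize gain
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = list(medoids)
    best_cost = D[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                cost = D[:, trial].min(axis=1).sum()
                if cost < best_cost - 1e-12:
                    medoids, best_cost, improved = trial, cost, True
        if not improved:
            break
    return np.argmin(D[:, medoids], axis=1)


def consensus_cluster(
    X: np.ndarray,
    k_range=(2, 3, 4, 5, 6),
    reps: int = 100,
    p_item: float = 0.8,
    method: str = "kmeans",
    seed: int = 0,
    delta_threshold: float = 0.10,
    force_k: int | None = None,
    deterministic_init: bool = False,
) -> ConsensusResult:
    """Run resampling consensus clustering over a range of k.

    Parameters
    ----------
    X
        Samples x features matrix (typically immune-cell fractions).
    reps, p_item
        Number of resampling iterations and the fraction of samples
        drawn (without replacement) in each.
    method
        ``kmeans`` (k-means++, 10 restarts per resample) or ``pam``.
    deterministic_init
        Seed the base clusterer from the iteration index only, so that
        with ``p_item=1`` the whole procedure is seed-independent.
    force_k
        Bypass automatic selection and use this k for the final labels.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_range = sorted(int(k) for k in k_range)
    if n < max(k_range) + 1:
        raise ValueError(f"need >= {max(k_range) + 1} samples, got {n}")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not 0 < p_item <= 1:
        raise ValueError("p_item must be in (0, 1]")

    rng = np.random.default_rng(seed)
    n_sub = max(int(round(p_item * n)), max(k_range) + 1)
    consensus: dict[int, np.ndarray] = {}
    resample_log: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for k in k_range:
        hits = np.zeros((n, n))
        tries = np.zeros((n, n))
        log: list[tuple[np.ndarray, np.ndarray]] = []
        for rep in range(reps):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False)) if p_item < 1 else np.arange(n)
            base_seed = rep if deterministic_init else int(rng.integers(2**31 - 1))
            if method == "kmeans":
                labels = KMeans(n_clusters=k, n_init=10, random_state=base_seed).fit_predict(X[idx])
            elif method == "pam":
                labels = _pam(X[idx], k, np.random.default_rng(base_seed))
            else:
                raise ValueError(f"unknown method {method!r}")
            tries[np.ix_(idx, idx)] += 1
            same = labels[:, None] == labels[None, :]
            hits[np.ix_(idx, idx)] += same
            log.append((idx.copy(), labels.copy()))
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(tries > 0, hits / np.maximum(tries, 1), 0.0)
        never = (tries == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            logger.warning(
                "%d sample pairs never co-sampled; consensus entries set to 0",
                int(never.sum()) // 2,
            )
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        consensus[k] = M
        resample_log[k] = log

    cdf = {k: consensus_cdf(consensus[k]) for k in k_range}
    area = {k: float(np.trapezoid(cdf[k], CDF_GRID)) for k in k_range}
    delta_area = {
        k_range[i]: (area[k_range[i + 1]] - area[k_range[i]]) / max(area[k_range[i]], 1e-12)
        for i in range(len(k_range) - 1)
    }

    result = ConsensusResult(
        k_range=k_range,
        consensus=consensus,
        cdf=cdf,
        area=area,
        delta_area=delta_area,
        chosen_k=0,
        labels=np.empty(0, dtype=int),
        method=method,
        reps=reps,
        p_item=p_item,
        resample_log=resample_log,
    )
    result.chosen_k = int(force_k) if force_k else select_k(result, delta_threshold)
    result.labels = _labels_from_consensus(consensus[result.chosen_k], result.chosen_k)
    return result


def consensus_cdf(consensus_matrix: np.ndarray) -> np.ndarray:
    """Empirical CDF of off-diagonal upper-triangle consensus entries.

    Evaluated at 101 grid points on [0, 1].
    """
    iu = np.triu_indices_from(consensus_matrix, k=1)
    vals = consensus_matrix[iu]
    if vals.size == 0:
        return np.ones_like(CDF_GRID)
    return np.searchsorted(np.sort(vals), CDF_GRID, side="right") / vals.size


def select_k(result: ConsensusResult, threshold: float = 0.10) -> int:
    """Pick the number of clusters from the consensus-CDF areas.

    ``delta_area[k]`` is the relative gain in area under the CDF when
    moving from k to k+1 clusters; the chosen k is the smallest one for
    which this gain falls below ``threshold`` (the CDF has flattened —
    extra clusters no longer sharpen the consensus). If the gain never
    drops below the threshold the maximum k is returned with a warning.
    """
    for k in result.k_range[:-1]:
        if result.delta_area[k] < threshold:
            return k
    warnings.warn("no consensus-CDF elbow found; returning max k", stacklevel=2)
    return result.k_range[-1]


def _labels_from_consensus(M: np.ndarray, k: int) -> np.ndarray:
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1
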