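"""Post-clustering of the trained codebook.

Following standard SOM-Toolbox practice, clusters are formed on the
codebook vectors (not the raw records) with k-means, validated by the
Davies-Bouldin index (lower is better), and the winning partition is
propagated to data records through their best matching units. Cluster ids
are 1-based, matching how map clusters are conventionally numbered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import Codebook
from .dataset import Dataset
from .errors import InputError

__all__ = [
    "ClusterResult",
    "kmeans_codebook",
    "davies_bouldin",
    "select_k",
    "assign_records",
    "cluster_map",
]


@dataclass
class ClusterResult:
    k: int
    unit_labels: np.ndarray  # per-unit cluster id in 1..k
    db_index: float
    centroids: np.ndarray  # (k, d)
    record_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unit_labels = np.asarray(self.unit_labels, dtype=int)
        present = set(np.unique(self.unit_labels).tolist())
        if present != set(range(1, self.k + 1)):
            raise InputError("every cluster id in 1..k must appear among unit labels")


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run from random distinct seeds; returns (labels0, centers, wcss).

    Empty clusters are repaired by re-seeding on the point farthest from its
    current center. WCSS is checked to be non-increasing across iterations.
    """
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    prev_wcss = np.inf
    wcss = np.inf
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        new_labels = d2.argmin(axis=1)
        repaired = False
        for j in range(k):
            if not np.any(new_labels == j):  # empty cluster: grab the worst-fit point
                repaired = True
                assigned = d2[np.arange(n), new_labels].copy()
                # never steal a point that is its cluster's sole member
                counts = np.bincount(new_labels, minlength=k)
                assigned[counts[new_labels] <= 1] = -np.inf
                farthest = int(assigned.argmax())
                centers[j] = X[farthest]
                new_labels[farthest] = j
                d2[:, j] = cdist(X, centers[j][None, :], "sqeuclidean")[:, 0]
        for j in range(k):
            centers[j] = X[new_labels == j].mean(axis=0)
        wcss = float(((X - centers[new_labels]) ** 2).sum())
        # Lloyd steps never increase WCSS; a repair resets the baseline
        if not repaired and wcss > prev_wcss + 1e-9 * (1.0 + prev_wcss):
            raise AssertionError("Lloyd iteration increased within-cluster sum of squares")
        if np.array_equal(new_labels, labels):
            break
        labels, prev_wcss = new_labels, wcss
    return labels, centers, wcss


def kmeans_codebook(
    codebook: Codebook | np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means on the codebook vectors; best of ``restarts`` by WCSS.

    Returns 1-based unit labels and the (k, d) centroid matrix;
    deterministic given the seed.
    """
    X = codebook.weights if isinstance(codebook, Codebook) else np.atleast_2d(np.asarray(codebook, dtype=float))
    n = X.shape[0]
    if not 2 <= k <= n:
        raise InputError(f"k must lie in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        labels, centers, wcss = _lloyd(X, k, rng)
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss)
    labels, centers, _ = best
    return labels + 1, centers


def davies_bouldin(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst pairwise
    (scatter_i + scatter_j) / ||centroid_i - centroid_j|| ratio.

    Scatter is the mean distance of a cluster's points to its own centroid.
    Labels may use any distinct values; their sorted order maps to centroid
    rows. Coincident centroids make the ratio undefined and raise.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    ids = np.unique(labels)
    k = ids.size
    if k != centroids.shape[0]:
        raise InputError("number of distinct labels must match number of centroids")
    if k < 2:
        raise InputError("Davies-Bouldin needs at least two clusters")
    scatter = np.empty(k)
    for j, lab in enumerate(ids):
        members = points[labels == lab]
        if members.size == 0:
            raise InputError("every cluster must be nonempty")
        scatter[j] = float(np.linalg.norm(members - centroids[j], axis=1).mean())
    sep = cdist(centroids, centroids)
    np.fill_diagonal(sep, np.inf)
    if np.any(sep == 0):
        raise InputError("coincident centroids: Davies-Bouldin ratio undefined")
    ratios = (scatter[:, None] + scatter[None, :]) / sep
    np.fill_diagonal(ratios, -np.inf)
    return float(ratios.max(axis=1).mean())


def select_k(
    codebook: Codebook,
    k_min: int = 2,
    k_max: int | None = None,
    seed: int = 0,
    restarts: int = 10,
) -> ClusterResult:
    """Sweep k in [k_min, k_max] and keep the partition with the smallest
    Davies-Bouldin index (ties -> smallest k).

    ``k_max`` defaults to sqrt(number of units), a standard heuristic for
    codebook-level clustering.
    """
    n_units = codebook.n_units
    if k_max is None:
        k_max = max(2, int(np.sqrt(n_units)))
    if not 2 <= k_min <= k_max <= n_units:
        raise InputError(f"need 2 <= k_min <= k_max <= {n_units}")
    best: ClusterResult | None = None
    for k in range(k_min, k_max + 1):
        k_seed = int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, k]).generate_state(1)[0] % (2**31))
        labels, centroids = kmeans_codebook(codebook, k, seed=k_seed, restarts=restarts)
        db = davies_bouldin(codebook.weights, labels, centroids)
        if best is None or db < best.db_index:
            best = ClusterResult(k=k, unit_labels=labels, db_index=db, centroids=centroids)
    return best


def assign_records(
    data: Dataset, codebook: Codebook, unit_labels: np.ndarray
) -> np.ndarray:
    """Propagate unit cluster labels to records through their BMUs."""
    unit_labels = np.asarray(unit_labels, dtype=int)
    if unit_labels.shape != (codebook.n_units,):
        raise InputError("unit_labels must cover every unit exactly once")
    if data.d != codebook.d:
        raise InputError("dataset and codebook dimensions differ")
    dist = cdist(data.values, codebook.weights)
    return unit_labels[dist.argmin(axis=1)]


def cluster_map(
    data: Dataset,
    codebook: Codebook,
    k_min: int = 2,
    k_max: int | None = None,
    seed: int = 0,
    restarts: int = 10,
    exclude_empty_units: bool = True,
) -> ClusterResult:
    """Data-aware k sweep on the codebook plus record assignment.

    By default only units that quantize at least one record (nonzero BMU
    hit count) participate in the k-means sweep and the Davies-Bouldin
    index; interpolating "dead" units sit between data clusters by
    construction and otherwise distort both. Dead units inherit the label
    of the nearest centroid so ``unit_labels`` still covers the whole map.
    """
    if data.d != codebook.d:
        raise InputError("dataset and codebook dimensions differ")
    W = codebook.weights
    dist = cdist(data.values, W)
    bmu = dist.argmin(axis=1)
    if exclude_empty_units:
        live = np.nonzero(np.bincount(bmu, minlength=codebook.n_units) > 0)[0]
    else:
        live = np.arange(codebook.n_units)
    n_live = live.size
    if k_max is None:
        k_max = max(2, int(np.sqrt(codebook.n_units)))
    k_max = min(k_max, n_live)
    if not 2 <= k_min <= k_max:
        raise InputError(f"need 2 <= k_min <= k_max <= {n_live} data-supporting units")
    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    for k in range(k_min, k_max + 1):
        k_seed = int(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, k]).generate_state(1)[0] % (2**31)
        )
        labels, centroids = kmeans_codebook(W[live], k, seed=k_seed, restarts=restarts)
        db = davies_bouldin(W[live], labels, centroids)
        if best is None or db < best[0]:
            best = (db, k, labels, centroids)
    db, k, live_labels, centroids = best
    unit_labels = np.empty(codebook.n_units, dtype=int)
    unit_labels[live] = live_labels
    dead = np.setdiff1d(np.arange(codebook.n_units), live)
    if dead.size:
        unit_labels[dead] = cdist(W[dead], centroids).argmin(axis=1) + 1
    result = ClusterResult(
        k=k, unit_labels=unit_labels, db_index=db, centroids=centroids
    )
    result.record_labels = unit_labels[bmu]
    return result
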