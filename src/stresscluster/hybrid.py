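"""Hierarchically initialized hybrid K-Means.

The number of clusters K is chosen by sweeping a range of candidate counts,
partitioning with the agglomerative hierarchy at each, and keeping the K
with the highest mean silhouette. The data are then agglomerated to
``K - split_budget`` clusters, whose recorded centers warm-start Lloyd's
algorithm; while fewer than K clusters exist, the least cohesive cluster —
the one with the largest class radius (maximum member-to-center distance) —
is split by farthest-point reseeding: the member x1 farthest from the
center, then the member x2 farthest from x1, replace the old center as two
new ones, and Lloyd refinement re-runs. The result is a standard K-Means
fixed point reached from a structured, deterministic initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data import ScoreMatrix
from .hierarchy import Partition, agglomerate, agglomerate_sweep

__all__ = [
    "Centroids",
    "HybridConfig",
    "LloydResult",
    "HybridResult",
    "mean_silhouette",
    "estimate_k",
    "cluster_radius",
    "split_cluster",
    "lloyd",
    "hybrid_fit",
]

Centroids = np.ndarray  # (k, m) array of cluster centers


@dataclass(frozen=True)
class HybridConfig:
    """Settings for :func:`hybrid_fit`.

    ``split_budget`` is the number of clusters held back from the
    agglomerative warm start and recovered by farthest-point splitting; it
    must satisfy ``0 <= split_budget < K - 2`` (and is forced to 0 when
    K = 2). When left unset it defaults to 1 for K >= 4 and 0 otherwise,
    and a configured value is clamped into the feasible range once K is
    known.
    """

    k_range: tuple[int, int] = (2, 6)
    split_budget: int | None = None
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid k_range {self.k_range}; need 2 <= lo <= hi")
        if self.split_budget is not None and self.split_budget < 0:
            raise ValueError("split_budget must be >= 0")
        if self.max_iter <= 0:
            raise ValueError("max_iter must be positive")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")

    def resolve_split_budget(self, k: int) -> int:
        cap = max(0, k - 3)  # 0 <= budget < k - 2
        if self.split_budget is None:
            return min(1, cap)
        return min(self.split_budget, cap)


@dataclass
class LloydResult:
    partition: Partition
    centroids: Centroids
    iterations: int
    sse: float
    sse_history: list[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class HybridResult:
    partition: Partition
    centroids: Centroids
    diagnostics: dict


def _pairwise(x: np.ndarray) -> np.ndarray:
    return cdist(x, x)


def mean_silhouette(scores: ScoreMatrix, part: Partition) -> float:
    """Mean silhouette coefficient of a partition, in [-1, 1].

    For each subject, a = mean distance to its own cluster's other members
    and b = smallest mean distance to another cluster; the silhouette is
    (b - a) / max(a, b). Members of singleton clusters contribute 0.
    """
    if part.n != scores.n_subjects:
        raise ValueError("partition size does not match score matrix")
    k = part.k
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = _pairwise(scores.values)
    labels = part.labels
    n = part.n
    sil = np.zeros(n)
    counts = np.bincount(labels, minlength=k)
    # mean distance from each point to each cluster
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = d[:, labels == c].sum(axis=1)
    for i in range(n):
        c = labels[i]
        if counts[c] == 1:
            sil[i] = 0.0
            continue
        a = sums[i, c] / (counts[c] - 1)
        b = np.inf
        for other in range(k):
            if other != c:
                b = min(b, sums[i, other] / counts[other])
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sil.mean())


def estimate_k(scores: ScoreMatrix, k_range: tuple[int, int]) -> int:
    """Pick K by the silhouette of agglomerative partitions.

    Runs the agglomerative hierarchy at every K in the (inclusive) range,
    scores each partition by mean silhouette, and returns the argmax;
    ties go to the smallest K.
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    if hi < lo:
        raise ValueError(f"empty k_range {k_range}")
    hi = min(hi, scores.n_subjects - 1)
    if hi < lo:
        raise ValueError(f"k_range {k_range} infeasible for n={scores.n_subjects}")
    snapshots = agglomerate_sweep(scores, lo, hi)
    best_k, best_s = lo, -np.inf
    for k in range(lo, hi + 1):
        s = mean_silhouette(scores, snapshots[k])
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def cluster_radius(scores: ScoreMatrix, members: Sequence[int], center: np.ndarray) -> float:
    """Largest member-to-center distance; the proxy for (inverse) cohesion."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("cluster has no members")
    d = np.linalg.norm(scores.values[members] - np.asarray(center, dtype=float), axis=1)
    return float(d.max())


def split_cluster(
    scores: ScoreMatrix, members: Sequence[int], center: np.ndarray
) -> tuple[int, int]:
    """Farthest-point pair used to reseed a split cluster.

    Returns (x1, x2): the member farthest from the center, then the member
    farthest from x1. Ties break to the lowest subject index (argmax picks
    the first maximum).
    """
    members = np.asarray(members, dtype=int)
    if members.size < 2:
        raise ValueError("cannot split a cluster with fewer than 2 members")
    pts = scores.values[members]
    d_center = np.linalg.norm(pts - np.asarray(center, dtype=float), axis=1)
    i1 = int(np.argmax(d_center))
    d_far = np.linalg.norm(pts - pts[i1], axis=1)
    d_far[i1] = -np.inf
    i2 = int(np.argmax(d_far))
    return int(members[i1]), int(members[i2])


def _assign(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # ties go to the lowest center index (argmin picks the first minimum)
    return np.argmin(cdist(x, centers), axis=1)


def lloyd(
    scores: ScoreMatrix,
    init: Centroids,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> LloydResult:
    """Lloyd's K-Means refinement from given initial centers.

    Alternates nearest-center assignment (Euclidean, ties to the lowest
    center index) with member-mean center updates until the largest center
    displacement is <= tol or max_iter is reached. A cluster left empty by
    an assignment is reseeded with the point farthest from its former
    center, so the cluster count never drops.
    """
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    x = scores.values
    centers = np.asarray(init, dtype=float).copy()
    if centers.ndim != 2 or centers.shape[1] != x.shape[1]:
        raise ValueError("init centers must be (k, m) with m matching the data")
    if not np.all(np.isfinite(centers)):
        raise ValueError("init centers must be finite")
    k = centers.shape[0]
    sse_history: list[float] = []
    labels = np.zeros(x.shape[0], dtype=int)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        labels = _assign(x, centers)
        # reseed empty clusters with the point farthest from the former center
        for _ in range(k):
            counts = np.bincount(labels, minlength=k)
            empty = np.nonzero(counts == 0)[0]
            if empty.size == 0:
                break
            c = int(empty[0])
            far = int(np.argmax(np.linalg.norm(x - centers[c], axis=1)))
            centers[c] = x[far]
            labels = _assign(x, centers)
        sse = float(np.sum((x - centers[labels]) ** 2))
        sse_history.append(sse)
        new_centers = centers.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new_centers[c] = x[mask].mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift <= tol:
            converged = True
            break
    labels = _assign(x, centers)
    part = Partition.from_labels(labels)
    # canonical labels may permute clusters; reorder centers to match
    order = np.empty(k, dtype=int)
    seen = np.zeros(k, dtype=bool)
    for i, lab in enumerate(labels):
        canon = part.labels[i]
        if not seen[canon]:
            order[canon] = lab
            seen[canon] = True
    centers = centers[order] if part.k == k else _recompute_centers(x, part)
    sse = float(np.sum((x - centers[part.labels]) ** 2))
    return LloydResult(part, centers, it, sse, sse_history, converged)


def _recompute_centers(x: np.ndarray, part: Partition) -> np.ndarray:
    centers = np.empty((part.k, x.shape[1]))
    for c, mem in enumerate(part.clusters()):
        centers[c] = x[mem].mean(axis=0)
    return centers


def hybrid_fit(scores: ScoreMatrix, cfg: HybridConfig | None = None) -> HybridResult:
    """Full hybrid pipeline: silhouette K, warm start, split, refine.

    Diagnostics record the chosen K, the resolved split budget, the number
    of splits performed, total Lloyd iterations, and the final
    within-cluster sum of squared distances (SSE).
    """
    cfg = cfg or HybridConfig()
    n = scores.n_subjects
    k = estimate_k(scores, cfg.k_range)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} subjects")
    budget = cfg.resolve_split_budget(k)
    part, tree = agglomerate(scores, k - budget)
    centers = np.asarray(tree.final_centers, dtype=float)
    splits = 0
    total_iters = 0
    result: LloydResult | None = None
    current_part = part
    while True:
        if centers.shape[0] < k:
            # split the least cohesive (largest-radius) splittable cluster
            radii = []
            for c, mem in enumerate(current_part.clusters()):
                r = cluster_radius(scores, mem, centers[c]) if mem.size else -np.inf
                radii.append(r if mem.size >= 2 else -np.inf)
            target = int(np.argmax(radii))
            if radii[target] == -np.inf:
                raise RuntimeError("no splittable cluster available")
            x1, x2 = split_cluster(scores, current_part.clusters()[target], centers[target])
            keep = np.delete(centers, target, axis=0)
            centers = np.vstack([keep, scores.values[x1], scores.values[x2]])
            splits += 1
        result = lloyd(scores, centers, cfg.max_iter, cfg.tol)
        total_iters += result.iterations
        current_part = result.partition
        centers = result.centroids
        if centers.shape[0] >= k:
            break
    diagnostics = {
        "k": int(k),
        "split_budget": int(budget),
        "splits": int(splits),
        "lloyd_iterations": int(total_iters),
        "sse": float(result.sse),
        "seed": int(cfg.seed),
        "sse_history": [float(v) for v in result.sse_history],
        "converged": bool(result.converged),
    }
    return HybridResult(result.partition, result.centroids, diagnostics)
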