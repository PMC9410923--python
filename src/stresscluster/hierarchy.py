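"""Agglomerative hierarchy with two-center averaging.

Starting from one singleton cluster per subject, the pair of clusters whose
*centers* are nearest in Euclidean distance is merged, and the new center is
computed from the two merged centers alone. Two update rules are offered:

``"weighted"`` (default)
    Size-weighted mean of the two centers. This equals the member mean of
    the merged cluster (centroid/UPGMC linkage) and is what the hybrid
    K-Means warm start uses: the recorded centers are genuine centroids.
``"midpoint"``
    Unweighted midpoint of the two centers (median/WPGMC linkage). Kept as
    an explicit option; its centers drift toward late small merges, which
    can strand outliers as singletons and merge well-separated groups, so
    it is not the default. Under this rule the final center of a full
    agglomeration is generally NOT the grand mean of the data.

Merge distances are recorded but no monotonicity is claimed: center-based
linkages can produce inversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data import ScoreMatrix

__all__ = ["Partition", "MergeRecord", "MergeTree", "agglomerate", "agglomerate_sweep"]


@dataclass(frozen=True)
class Partition:
    """Assignment of n subjects to contiguous 0-based cluster labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D integer array")
        uniq = np.unique(labels)
        if uniq[0] != 0 or uniq[-1] != uniq.size - 1:
            raise ValueError("labels must be contiguous integers 0..k-1")

    @classmethod
    def from_labels(cls, labels: Iterable[int]) -> "Partition":
        """Canonicalize arbitrary labels: renumber by first appearance."""
        raw = np.asarray(list(labels))
        _, first = np.unique(raw, return_index=True)
        order = raw[np.sort(first)]
        remap = {lab: i for i, lab in enumerate(order)}
        return cls(np.array([remap[lab] for lab in raw], dtype=int))

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1

    def clusters(self) -> list[np.ndarray]:
        """Member indices per cluster, ordered by label."""
        return [np.nonzero(self.labels == c)[0] for c in range(self.k)]

    def as_id_clusters(self, subject_ids: Sequence[str]) -> list[list[str]]:
        return [[subject_ids[i] for i in members] for members in self.clusters()]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)


@dataclass(frozen=True)
class MergeRecord:
    level: int
    pair: tuple[int, int]
    new_center: np.ndarray
    distance: float


@dataclass
class MergeTree:
    """Ordered record of agglomerative merges.

    Singleton clusters carry ids ``0..n-1`` in subject order; the cluster
    created at merge level ``t`` (0-based) gets id ``n + t``. ``final_centers``
    holds the centers of the clusters still active when merging stopped,
    aligned with the labels of the returned :class:`Partition`.
    """

    n_leaves: int
    records: list[MergeRecord] = field(default_factory=list)
    final_centers: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_dict(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "merges": [
                {
                    "level": r.level,
                    "pair": list(r.pair),
                    "new_center": [float(v) for v in r.new_center],
                    "distance": float(r.distance),
                }
                for r in self.records
            ],
        }

    def to_newick(self, subject_ids: Sequence[str]) -> str:
        """Nested-parenthesis rendering of the merge structure.

        Branch lengths are the recorded merge distances; only meaningful
        when the tree was built down to a single cluster.
        """
        node: dict[int, str] = {i: str(subject_ids[i]) for i in range(self.n_leaves)}
        for r in self.records:
            a, b = r.pair
            new_id = self.n_leaves + r.level
            node[new_id] = f"({node.pop(a)},{node.pop(b)}):{r.distance:.6g}"
        return "(" + ",".join(node[i] for i in sorted(node)) + ");"


def _snapshot(members: list[list[int]], n: int) -> Partition:
    labels = np.empty(n, dtype=int)
    for pos, mem in enumerate(members):
        labels[mem] = pos
    return Partition.from_labels(labels)


def agglomerate(
    scores: ScoreMatrix,
    stop_k: int,
    center_update: str = "weighted",
    _snapshot_ks: frozenset[int] = frozenset(),
    _snapshots: dict[int, Partition] | None = None,
) -> tuple[Partition, MergeTree]:
    """Merge nearest-center cluster pairs until ``stop_k`` clusters remain.

    Ties on the merge distance are broken by the lexicographically lowest
    pair of cluster ids, which makes the result deterministic and stable
    under subject order when all pairwise distances are distinct.
    """
    n = scores.n_subjects
    if not 1 <= stop_k <= n:
        raise ValueError(f"stop_k must be in [1, {n}], got {stop_k}")
    if center_update not in ("weighted", "midpoint"):
        raise ValueError(f"unknown center_update {center_update!r}")
    x = scores.values
    # active clusters ordered by ascending id
    ids = list(range(n))
    centers = [x[i].copy() for i in range(n)]
    members = [[i] for i in range(n)]
    sizes = [1] * n
    tree = MergeTree(n_leaves=n)
    level = 0
    while len(ids) > stop_k:
        if _snapshots is not None and len(ids) in _snapshot_ks:
            _snapshots[len(ids)] = _snapshot(members, n)
        c = np.asarray(centers)
        d = cdist(c, c)
        iu = np.triu_indices(len(ids), k=1)
        flat = d[iu]
        best = int(np.argmin(flat))  # first occurrence = lexicographically lowest pair
        i, j = int(iu[0][best]), int(iu[1][best])
        if center_update == "weighted":
            si, sj = sizes[i], sizes[j]
            new_center = (si * centers[i] + sj * centers[j]) / (si + sj)
        else:
            new_center = 0.5 * (centers[i] + centers[j])
        rec = MergeRecord(
            level=level,
            pair=(ids[i], ids[j]),
            new_center=new_center,
            distance=float(flat[best]),
        )
        tree.records.append(rec)
        new_members = members[i] + members[j]
        new_size = sizes[i] + sizes[j]
        # drop j first (j > i) so indices stay valid
        for pos in (j, i):
            del ids[pos], centers[pos], members[pos], sizes[pos]
        ids.append(n + level)
        centers.append(new_center)
        members.append(new_members)
        sizes.append(new_size)
        level += 1
    part = _snapshot(members, n)
    if _snapshots is not None and len(ids) in _snapshot_ks:
        _snapshots[len(ids)] = part
    # reorder centers to match canonical labels
    ordered = np.empty((len(ids), x.shape[1]))
    for pos, mem in enumerate(members):
        ordered[part.labels[mem[0]]] = centers[pos]
    tree.final_centers = ordered
    return part, tree


def agglomerate_sweep(
    scores: ScoreMatrix, lo: int, hi: int, center_update: str = "weighted"
) -> dict[int, Partition]:
    """Partitions at every cluster count in [lo, hi] from one merge pass.

    The greedy merge sequence does not depend on where it stops, so a
    single agglomeration to ``lo`` clusters passes through the partition
    that ``agglomerate(scores, k)`` would return for every k >= lo.
    """
    n = scores.n_subjects
    if not 1 <= lo <= hi <= n:
        raise ValueError(f"need 1 <= lo <= hi <= {n}, got [{lo}, {hi}]")
    snapshots: dict[int, Partition] = {}
    agglomerate(scores, lo, center_update, frozenset(range(lo, hi + 1)), snapshots)
    return snapshots
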