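"""Fuzzy equivalence-relation clustering.

Pairwise similarity between subjects is built attribute-wise: each
attribute difference is normalized by that attribute's observed range, the
per-attribute distances are combined as a root-mean-square, and similarity
is one minus that distance. The resulting fuzzy similarity relation is
reflexive and symmetric but not min-transitive, so thresholding it directly
does not partition the subjects. Its max-min transitive closure — computed
by repeated self-composition ("squaring") until idempotent — is the smallest
min-transitive relation containing it; cutting the closure at any threshold
λ yields a genuine partition, and sweeping λ over the closure's distinct
values produces a nested hierarchy of partitions (the system clustering
diagram).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .data import ScoreMatrix
from .hierarchy import Partition

__all__ = [
    "FuzzyRelation",
    "ThresholdHierarchy",
    "euclidean_distance",
    "attribute_distance",
    "similarity_matrix",
    "transitive_closure",
    "lambda_cut",
    "threshold_sweep",
]

_SYM_TOL = 1e-12


def euclidean_distance(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Plain Euclidean distance between two attribute vectors."""
    a = np.asarray(x_i, dtype=float)
    b = np.asarray(x_j, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def attribute_distance(x_ik: float, x_jk: float, a_kmax: float, a_kmin: float) -> float:
    """Range-normalized distance on a single attribute, in [0, 1]."""
    if not a_kmax > a_kmin:
        raise ValueError("attribute range must be positive (constant attribute?)")
    return abs(x_ik - x_jk) / (a_kmax - a_kmin)


@dataclass
class FuzzyRelation:
    """Symmetric reflexive n x n relation with entries in [0, 1].

    Houses both the similarity matrix S and its transitive closure T.
    """

    matrix: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        self.matrix = m
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("relation matrix must be square")
        if len(self.subject_ids) != m.shape[0]:
            raise ValueError("subject_ids length does not match matrix size")
        if m.min() < -_SYM_TOL or m.max() > 1 + _SYM_TOL:
            raise ValueError("relation entries must lie in [0, 1]")
        if not np.allclose(np.diag(m), 1.0, atol=_SYM_TOL):
            raise ValueError("relation must be reflexive (unit diagonal)")
        if not np.allclose(m, m.T, atol=_SYM_TOL):
            raise ValueError("relation must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def is_min_transitive(self, tol: float = _SYM_TOL) -> bool:
        """Check t(i,k) >= min(t(i,j), t(j,k)) for all triples."""
        m = self.matrix
        composed = np.minimum(m[:, :, None], m[None, :, :]).max(axis=1)
        return bool(np.all(m >= composed - tol))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.subject_ids, columns=self.subject_ids)


def similarity_matrix(scores: ScoreMatrix) -> FuzzyRelation:
    """Fuzzy similarity relation from a score table.

    ``d(i,j) = sqrt( mean_k d_k(i,j)^2 )`` with ``d_k`` the range-normalized
    attribute distance, and ``s(i,j) = 1 - d(i,j)``. The diagonal is exactly 1
    and all entries lie in [0, 1]. Constant attributes are rejected.
    """
    x = scores.values
    col_min = x.min(axis=0)
    col_max = x.max(axis=0)
    rng = col_max - col_min
    const = np.nonzero(rng == 0)[0]
    if const.size:
        raise ValueError(
            f"constant attribute column {scores.attribute_names[const[0]]!r}: "
            "zero range breaks the attribute-wise normalization"
        )
    norm = x / rng  # shift cancels in differences
    diff = norm[:, None, :] - norm[None, :, :]
    d = np.sqrt(np.mean(diff**2, axis=2))
    s = 1.0 - d
    np.fill_diagonal(s, 1.0)
    s = np.clip(s, 0.0, 1.0)
    s = 0.5 * (s + s.T)  # enforce exact symmetry against round-off
    return FuzzyRelation(s, list(scores.subject_ids))


def transitive_closure(rel: FuzzyRelation, max_rounds: int | None = None) -> FuzzyRelation:
    """Max-min transitive closure by repeated squaring.

    Replaces R by R∘R, where ``(R∘R)(i,j) = max_k min(R(i,k), R(k,j))``,
    until a fixed point. Because max-min composition only ever selects
    values already present in the matrix, the fixed-point test is exact.
    Convergence needs at most ``ceil(log2(n-1)) + 1`` squarings.
    """
    r = rel.matrix.copy()
    n = r.shape[0]
    if max_rounds is None:
        max_rounds = max(1, int(np.ceil(np.log2(max(n - 1, 1)))) + 2)
    for _ in range(max_rounds):
        squared = np.minimum(r[:, :, None], r[None, :, :]).max(axis=1)
        if np.array_equal(squared, r):
            break
        r = squared
    else:  # pragma: no cover - the bound above guarantees convergence
        raise RuntimeError("transitive closure failed to converge")
    return FuzzyRelation(r, list(rel.subject_ids))


def lambda_cut(closure: FuzzyRelation, lam: float) -> Partition:
    """Partition subjects by the equivalence ``i ~ j  iff  t(i,j) >= lam``.

    The threshold is closed (>=): pairs sitting exactly at λ share a
    cluster. Requires a min-transitive relation — on a non-transitive
    relation the cut need not be an equivalence, so it is rejected.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if not closure.is_min_transitive():
        raise ValueError("lambda_cut requires a min-transitive relation; apply transitive_closure first")
    adj = csr_matrix(closure.matrix >= lam)
    _, comp = connected_components(adj, directed=False)
    return Partition.from_labels(comp)


@dataclass
class ThresholdHierarchy:
    """Nested partitions from cutting a closure at every distinct value.

    ``levels`` is ordered by strictly decreasing λ; the partition at a
    larger λ refines the partition at any smaller λ.
    """

    levels: list[tuple[float, Partition]]
    subject_ids: list[str]

    def __len__(self) -> int:
        return len(self.levels)

    def partition_at(self, lam: float) -> Partition:
        """Partition for an arbitrary λ.

        Only pairs with t(i,j) >= λ are joined, so the cut at λ equals the
        recorded cut at the smallest grid value >= λ.
        """
        chosen = None
        for value, part in self.levels:  # descending
            if value >= lam:
                chosen = part
            else:
                break
        if chosen is None:
            # λ above every entry (λ > 1): all singletons
            return Partition.from_labels(range(len(self.subject_ids)))
        return chosen

    def to_json(self) -> str:
        payload = [
            {"lambda": value, "clusters": part.as_id_clusters(self.subject_ids)}
            for value, part in self.levels
        ]
        return json.dumps(payload, indent=2)


def threshold_sweep(closure: FuzzyRelation) -> ThresholdHierarchy:
    """Cut the closure at each of its distinct entry values, descending."""
    if not closure.is_min_transitive():
        raise ValueError("threshold_sweep requires a min-transitive relation")
    grid = np.unique(closure.matrix)[::-1]
    levels = [(float(lam), lambda_cut(closure, float(lam))) for lam in grid]
    return ThresholdHierarchy(levels, list(closure.subject_ids))
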