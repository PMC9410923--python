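"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: the closure oracle
enumerates simple paths, and the partition helpers enumerate assignments.
"""

from itertools import permutations

import numpy as np


def brute_closure(R: np.ndarray) -> np.ndarray:
    """Max over all simple paths of the minimum edge weight, per pair."""
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    T = R.copy()
    for i in range(n):
        for j in range(i + 1, n):
            best = R[i, j]
            others = [k for k in range(n) if k not in (i, j)]
            for r in range(1, len(others) + 1):
                for mid in permutations(others, r):
                    path = (i, *mid, j)
                    w = min(R[a][b] for a, b in zip(path, path[1:]))
                    if w > best:
                        best = w
            T[i, j] = T[j, i] = best
    return T


def random_grid_relation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric reflexive relation with entries on the 0.1 grid."""
    vals = rng.integers(0, 11, size=(n, n)) / 10.0
    R = np.minimum(vals, vals.T)
    np.fill_diagonal(R, 1.0)
    return R


def brute_best_match_accuracy(pred_labels, truth_labels) -> float:
    """Exhaustive max over one-to-one label mappings (small k only)."""
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    pk = pred_labels.max() + 1
    tk = truth_labels.max() + 1
    big = max(pk, tk)
    best = 0
    for perm in permutations(range(big), int(pk)):
        correct = sum(
            1 for p, t in zip(pred_labels, truth_labels) if perm[p] == t
        )
        best = max(best, correct)
    return best / pred_labels.size
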