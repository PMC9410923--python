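"""Synthetic labeled datasets and the packaged athlete fixture.

The generator draws k spherical Gaussian clusters (unit within-cluster
standard deviation) in m dimensions, with centers placed so their pairwise
separation is ``separation`` standard deviations, then affinely rescales
each attribute onto the [0, 10] working scale. Affine rescaling — rather
than clipping — preserves the mixture geometry, so the generating labels
remain the ground truth for recovery experiments. When k <= m the centers
sit on scaled coordinate axes and every pairwise distance equals the
requested separation exactly; for k > m centers are drawn isotropically at
random and rescaled so the *minimum* pairwise distance matches.

The 10-athlete, 6-stressor score table used throughout the worked examples
ships as a packaged CSV (``table2_fixture``). A three-dataset benchmark
suite with (n, k) = (150, 3), (300, 2), (4000, 30) mirrors the shapes of
the classic Iris / Breast Cancer / Abalone evaluation trio without any
download; it makes no attempt to emulate those datasets' actual feature
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .data import ScaleSpec, ScoreMatrix, linear_rescale, load_score_table
from .hierarchy import Partition

__all__ = [
    "LabeledDataset",
    "generate_labeled",
    "generate_hard_mixture",
    "table2_fixture",
    "benchmark_suite",
]

#: separation (in within-cluster standard deviations) for the benchmark suite
BENCHMARK_SEPARATION = 6.0
BENCHMARK_SHAPES = [(150, 3), (300, 2), (4000, 30)]
BENCHMARK_M = 4


@dataclass
class LabeledDataset:
    scores: ScoreMatrix
    truth: Partition
    n: int
    k: int
    m: int
    separation: float
    seed: int


def _place_centers(k: int, m: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    if separation == 0 or k == 1:
        return np.zeros((k, m))
    if k <= m:
        centers = np.zeros((k, m))
        for i in range(k):
            centers[i, i] = separation / np.sqrt(2)  # all pairwise distances == separation
        return centers
    centers = rng.standard_normal((k, m))
    diffs = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=2))
    dmin = dist[np.triu_indices(k, 1)].min()
    if dmin == 0:  # pragma: no cover - probability zero
        raise RuntimeError("degenerate random center placement")
    return centers * (separation / dmin)


def generate_labeled(
    n: int, k: int, m: int, separation: float, seed: int
) -> LabeledDataset:
    """Labeled Gaussian-mixture score table on [0, 10].

    Cluster sizes are as equal as possible; the draw is fully determined by
    ``seed``. ``separation`` is the inter-center distance in units of the
    within-cluster standard deviation (the minimum such distance when
    k > m).
    """
    if not (n >= k >= 1):
        raise ValueError(f"need n >= k >= 1, got n={n}, k={k}")
    if m < 1:
        raise ValueError("m must be >= 1")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    centers = _place_centers(k, m, separation, rng)
    base, extra = divmod(n, k)
    sizes = [base + (1 if c < extra else 0) for c in range(k)]
    labels = np.repeat(np.arange(k), sizes)
    points = centers[labels] + rng.standard_normal((n, m))
    scores = linear_rescale(
        points,
        ScaleSpec(),
        subject_ids=[f"S{i + 1}" for i in range(n)],
        attribute_names=[f"M{j + 1}" for j in range(m)],
    )
    return LabeledDataset(
        scores=scores,
        truth=Partition.from_labels(labels),
        n=n,
        k=k,
        m=m,
        separation=float(separation),
        seed=int(seed),
    )


#: the "hard" mixture used for initialization-quality comparisons: many
#: clusters at low separation, where random seeding often doubles up
#: centers in one group and misses another
HARD_MIXTURE = {"n": 160, "k": 8, "m": 4, "separation": 3.0}


def generate_hard_mixture(seed: int) -> LabeledDataset:
    """Overlapping 8-cluster mixture where initialization quality matters.

    With only a few well-separated clusters, K-Means converges to the same
    optimum from almost any start and initialization comparisons are
    tie-dominated; with many clusters at separation 3 the random-start
    failure mode (two centers in one group, none in another) occurs often
    enough to measure.
    """
    return generate_labeled(seed=seed, **HARD_MIXTURE)


def table2_fixture() -> ScoreMatrix:
    """The 10-athlete x 6-stressor score table, IDs A1-A10, sources M1-M6."""
    with resources.as_file(
        resources.files("stresscluster").joinpath("data/table2.csv")
    ) as path:
        return load_score_table(path)


def benchmark_suite(seed: int) -> list[LabeledDataset]:
    """Three labeled datasets shaped (150, 3), (300, 2), (4000, 30)."""
    seeds = np.random.SeedSequence(seed).generate_state(len(BENCHMARK_SHAPES)) % (2**31)
    return [
        generate_labeled(n, k, BENCHMARK_M, BENCHMARK_SEPARATION, int(s))
        for (n, k), s in zip(BENCHMARK_SHAPES, seeds)
    ]
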