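"""Weighted composite stress index and acute/chronic source aggregation.

A subject's stress index is the weight-normalized sum of their per-source
scores, Q = Σ w_i e_i / Σ w_i, so Q always lies between the smallest and
largest score. Weights reflect how strongly a source bears on competitive
performance; an exponential scheme w_i = base^(n_i) grows a source's weight
with the number of times that kind of pressure recurs across subjects.
Sources are classified as *acute* (competition-originating) or *chronic*
(external, long-running), and each class's share of total weighted pressure
is reported alongside the per-subject indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import ScoreMatrix

__all__ = [
    "WeightScheme",
    "SourceTaxonomy",
    "StressReport",
    "stress_index",
    "exponential_weights",
    "class_shares",
    "DEFAULT_BANDS",
]

PRESSURE_CLASSES = ("acute", "chronic")

#: Interpretation bands on the [0, 10] working scale: low / medium / high.
DEFAULT_BANDS = {"low": (0.0, 4.0), "medium": (4.0, 7.0), "high": (7.0, 10.0)}


@dataclass(frozen=True)
class WeightScheme:
    """Positive per-source weights, optionally from an exponential generator."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(w <= 0):
            raise ValueError("all weights must be positive")

    @classmethod
    def uniform(cls, m: int) -> "WeightScheme":
        return cls(np.full(m, 1.0 / m))

    @classmethod
    def from_counts(cls, n_counts: Sequence[int], base: float) -> "WeightScheme":
        return cls(exponential_weights(n_counts, base))

    @property
    def m(self) -> int:
        return self.weights.size

    def normalized(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def exponential_weights(n_counts: Sequence[int], base: float) -> np.ndarray:
    """w_i = base^(n_i), normalized to sum to 1.

    ``n_counts`` are the repetition counts of each kind of pressure across
    the subject pool; a source that recurs more often weighs more.
    """
    if not base > 1:
        raise ValueError(f"base must exceed 1, got {base}")
    counts = np.asarray(n_counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("n_counts must be a non-empty 1-D sequence")
    if np.any(counts < 0):
        raise ValueError("repetition counts must be non-negative")
    w = np.power(base, counts)
    return w / w.sum()


def stress_index(e: Sequence[float], w: WeightScheme | Sequence[float]) -> float:
    """Composite index Q = Σ w_i e_i / Σ w_i for one subject."""
    scores = np.asarray(e, dtype=float)
    weights = w.weights if isinstance(w, WeightScheme) else np.asarray(w, dtype=float)
    if scores.shape != weights.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and weights must be 1-D of equal positive length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.dot(weights, scores) / weights.sum())


@dataclass(frozen=True)
class SourceTaxonomy:
    """Total mapping from stressor attribute to 'acute' or 'chronic'."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in PRESSURE_CLASSES}
        if bad:
            raise ValueError(f"unknown pressure classes {sorted(bad)}; use {PRESSURE_CLASSES}")

    def class_of(self, attribute: str) -> str:
        try:
            return self.mapping[attribute]
        except KeyError:
            raise ValueError(f"attribute {attribute!r} is not classified") from None


@dataclass
class StressReport:
    """Per-subject indices plus class-level aggregate shares."""

    subject_ids: list[str]
    q: np.ndarray
    shares: dict[str, float]
    weights: np.ndarray
    taxonomy: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "subjects": [
                {"id": sid, "Q": float(v)} for sid, v in zip(self.subject_ids, self.q)
            ],
            "shares": {k: float(v) for k, v in self.shares.items()},
            "weights": [float(v) for v in self.weights],
            "taxonomy": dict(self.taxonomy),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def class_shares(
    scores: ScoreMatrix,
    w: WeightScheme | None,
    tax: SourceTaxonomy | Mapping[str, str],
) -> StressReport:
    """Aggregate weighted pressure into acute vs. chronic shares.

    share(class) = Σ_{sources in class} Σ_subjects w_i e_i, normalized over
    all sources, so the shares sum to 1. Uniform rescaling of the weights
    leaves the shares unchanged. Per-subject Q is reported alongside.
    """
    if not isinstance(tax, SourceTaxonomy):
        tax = SourceTaxonomy(dict(tax))
    w = w or WeightScheme.uniform(scores.n_attributes)
    if w.m != scores.n_attributes:
        raise ValueError("weight count does not match number of attributes")
    classes = [tax.class_of(a) for a in scores.attribute_names]
    weights = w.weights
    weighted_totals = weights * scores.values.sum(axis=0)  # per source
    total = weighted_totals.sum()
    shares = {c: 0.0 for c in PRESSURE_CLASSES}
    for cls_name, wt in zip(classes, weighted_totals):
        shares[cls_name] += float(wt)
    if total > 0:
        shares = {c: v / total for c, v in shares.items()}
    q = scores.values @ weights / weights.sum()
    return StressReport(
        subject_ids=list(scores.subject_ids),
        q=q,
        shares=shares,
        weights=weights.copy(),
        taxonomy={a: c for a, c in zip(scores.attribute_names, classes)},
    )
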