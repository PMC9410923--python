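"""Core data types and I/O for subject-by-stressor score tables.

A score table holds *n* subjects (athletes) measured on *m* stressor
attributes, every value on a common bounded scale (by default ``[0, 10]``).
Raw questionnaire totals are brought onto that scale with a per-attribute
linear (affine min-max) rescaling, so the attribute-wise range
normalization used downstream in the fuzzy similarity construction never
divides by zero and every attribute spans the full working scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ScaleSpec", "ScoreMatrix", "load_score_table", "linear_rescale"]

_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class ScaleSpec:
    """Closed interval the working scores live on."""

    lower: float = 0.0
    upper: float = 10.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"scale lower bound must be below upper bound, got "
                f"[{self.lower}, {self.upper}]"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class ScoreMatrix:
    """n subjects x m stressor attributes, values on a fixed bounded scale.

    Parameters
    ----------
    subject_ids
        Ordered subject identifiers (length n, unique).
    attribute_names
        Ordered stressor names (length m, unique).
    values
        ``(n, m)`` float array; every entry finite and within ``scale``.
    scale
        The declared working scale; defaults to ``[0, 10]``.
    """

    subject_ids: list[str]
    attribute_names: list[str]
    values: np.ndarray
    scale: ScaleSpec = field(default_factory=ScaleSpec)

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.attribute_names = [str(a) for a in self.attribute_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("score matrix needs at least one subject and one attribute")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")
        if len(self.attribute_names) != m:
            raise ValueError("attribute_names length does not match number of columns")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject identifiers")
        if len(set(self.attribute_names)) != m:
            raise ValueError("duplicate attribute names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains missing or non-finite entries")
        lo, hi = self.scale.lower, self.scale.upper
        if self.values.min() < lo - _BOUND_TOL or self.values.max() > hi + _BOUND_TOL:
            raise ValueError(
                f"scores fall outside the declared scale [{lo}, {hi}]; "
                "rescale raw data with linear_rescale first"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="id"),
            columns=self.attribute_names,
        )

    def row(self, subject_id: str) -> np.ndarray:
        return self.values[self.subject_ids.index(subject_id)]

    def value(self, subject_id: str, attribute: str) -> float:
        i = self.subject_ids.index(subject_id)
        j = self.attribute_names.index(attribute)
        return float(self.values[i, j])


def load_score_table(path: str | Path, scale: ScaleSpec | None = None) -> ScoreMatrix:
    """Read a score table from CSV.

    The file must have a header row; the first column is the subject ID and
    every remaining column is numeric. Missing cells, non-numeric cells and
    duplicate IDs raise ``ValueError`` naming the offending row/column.
    """
    scale = scale or ScaleSpec()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an ID column plus at least one attribute column")
    ids = df.iloc[:, 0].astype(str)
    if ids.size == 0:
        raise ValueError(f"{path}: no data rows")
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject ID {dup.iloc[0]!r}")
    attrs = list(df.columns[1:])
    body = df.iloc[:, 1:].copy()
    for col in attrs:
        numeric = pd.to_numeric(body[col], errors="coerce")
        bad = numeric.isna() & body[col].notna()
        if bad.any():
            row_id = ids[bad].iloc[0]
            raise ValueError(f"{path}: non-numeric cell at row {row_id!r}, column {col!r}")
        missing = numeric.isna()
        if missing.any():
            row_id = ids[missing].iloc[0]
            raise ValueError(f"{path}: missing value at row {row_id!r}, column {col!r}")
        body[col] = numeric
    return ScoreMatrix(list(ids), attrs, body.to_numpy(dtype=float), scale)


def linear_rescale(
    raw: np.ndarray | pd.DataFrame | ScoreMatrix,
    scale: ScaleSpec | None = None,
    *,
    subject_ids: Sequence[str] | None = None,
    attribute_names: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Affinely map each attribute column onto the working scale.

    Per column, ``x' = lower + (upper - lower) * (x - min) / (max - min)``,
    so the column minimum lands on the scale's lower bound and the maximum
    on its upper bound. Rank order within a column is preserved exactly and
    the map is idempotent on already-rescaled columns.

    A constant column raises ``ValueError``: it carries no clustering
    information and its zero range would break the attribute-wise
    normalization downstream.
    """
    scale = scale or ScaleSpec()
    if isinstance(raw, ScoreMatrix):
        subject_ids = raw.subject_ids
        attribute_names = raw.attribute_names
        x = raw.values
    elif isinstance(raw, pd.DataFrame):
        subject_ids = subject_ids or [str(i) for i in raw.index]
        attribute_names = attribute_names or [str(c) for c in raw.columns]
        x = raw.to_numpy(dtype=float)
    else:
        x = np.asarray(raw, dtype=float)
        if x.ndim != 2:
            raise ValueError("raw matrix must be 2-D")
        subject_ids = subject_ids or [f"S{i + 1}" for i in range(x.shape[0])]
        attribute_names = attribute_names or [f"M{j + 1}" for j in range(x.shape[1])]
    col_min = x.min(axis=0)
    col_max = x.max(axis=0)
    rng = col_max - col_min
    const = np.nonzero(rng == 0)[0]
    if const.size:
        name = list(attribute_names)[const[0]]
        raise ValueError(f"constant attribute column {name!r}: cannot rescale a zero range")
    scaled = scale.lower + scale.width * (x - col_min) / rng
    # guard against round-off creeping a hair past the bounds
    scaled = np.clip(scaled, scale.lower, scale.upper)
    return ScoreMatrix(list(subject_ids), list(attribute_names), scaled, scale)
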