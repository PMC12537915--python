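"""Core domain types for composite-indicator decision analysis.

A *decision matrix* holds the raw evaluations ``x_ij`` of ``m`` alternatives
(e.g. countries) on ``n`` criteria (e.g. safety performance indicators).
Each criterion carries a direction: *benefit* (larger raw values are better)
or *cost* (smaller raw values are better). Downstream stages consume a
*normalized matrix* (common [0, 1]-ish scale, direction folded in), a
*weight vector* (non-negative, sums to one), a *score table* (weighted-sum,
weighted-product and blended WASPAS scores with ranks) and a *grouping
result* (k-means labels and centers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DuplicateIdError,
    NonNumericCellError,
    ShapeMismatchError,
    ValidationError,
)

BENEFIT = "benefit"
COST = "cost"

NORMALIZATION_METHODS = ("logistic", "fuzzy_quantization", "decimal_scaling", "vector")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if not i:
            raise ValidationError(f"empty {what} id")
        if i in seen:
            raise DuplicateIdError(f"duplicate {what} id {i!r}")
        seen.add(i)


def _as_float_matrix(values, m: int, n: int) -> np.ndarray:
    try:
        arr = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise NonNumericCellError(str(exc)) from exc
    if arr.shape != (m, n):
        raise ShapeMismatchError(f"values shape {arr.shape} != ({m}, {n})")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise NonNumericCellError(
            f"non-finite value at row {bad[0]}, column {bad[1]}"
        )
    return arr


@dataclass(frozen=True)
class CriterionSpec:
    """Identity and orientation of one criterion."""

    id: str
    direction: str = BENEFIT
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("criterion id must be non-empty")
        if self.direction not in (BENEFIT, COST):
            raise ValidationError(
                f"direction must be {BENEFIT!r} or {COST!r}, got {self.direction!r}"
            )


@dataclass(frozen=True)
class DecisionMatrix:
    """Raw m-by-n evaluation table with criterion directions.

    Invariants enforced at construction: m >= 2, n >= 1, unique ids,
    all entries finite.
    """

    alternatives: tuple[str, ...]
    criteria: tuple[CriterionSpec, ...]
    values: np.ndarray

    def __init__(self, alternatives, criteria, values):
        alternatives = tuple(alternatives)
        criteria = tuple(
            c if isinstance(c, CriterionSpec) else CriterionSpec(str(c))
            for c in criteria
        )
        if len(alternatives) < 2:
            raise ValidationError("need at least 2 alternatives")
        if len(criteria) < 1:
            raise ValidationError("need at least 1 criterion")
        _check_unique(alternatives, "alternative")
        _check_unique([c.id for c in criteria], "criterion")
        arr = _as_float_matrix(values, len(alternatives), len(criteria))
        arr.setflags(write=False)
        object.__setattr__(self, "alternatives", alternatives)
        object.__setattr__(self, "criteria", criteria)
        object.__setattr__(self, "values", arr)

    @property
    def m(self) -> int:
        return len(self.alternatives)

    @property
    def n(self) -> int:
        return len(self.criteria)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(c.direction for c in self.criteria)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, type(self))
            and self.alternatives == other.alternatives
            and self.criteria == other.criteria
            and np.array_equal(self.values, other.values)
        )


class NormalizedMatrix(DecisionMatrix):
    """A decision matrix mapped onto a common scale; records the method."""

    method: str

    def __init__(self, alternatives, criteria, values, method: str):
        if method not in NORMALIZATION_METHODS:
            raise ValidationError(f"unknown normalization method {method!r}")
        super().__init__(alternatives, criteria, values)
        object.__setattr__(self, "method", method)

    def __eq__(self, other) -> bool:
        return super().__eq__(other) and self.method == other.method


@dataclass(frozen=True)
class WeightVector:
    """Objective per-criterion weights; non-negative, summing to one."""

    weights: np.ndarray
    method: str
    criterion_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ShapeMismatchError("weights must be 1-D")
        if np.any(w < -1e-15):
            raise ValidationError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")
        w = np.clip(w, 0.0, None)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        if self.criterion_ids is not None:
            ids = tuple(self.criterion_ids)
            if len(ids) != w.size:
                raise ShapeMismatchError("criterion_ids length != weights length")
            object.__setattr__(self, "criterion_ids", ids)

    def __len__(self) -> int:
        return self.weights.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightVector)
            and self.method == other.method
            and self.criterion_ids == other.criterion_ids
            and np.allclose(self.weights, other.weights, rtol=0, atol=1e-15)
        )


@dataclass(frozen=True)
class ScoreTable:
    """Per-alternative WASPAS scores and ranks.

    ``wq = lam * ws + (1 - lam) * wp``; ranks are competition ranks
    (1 = best, ties share the smallest rank) on descending ``wq``.
    """

    alternatives: tuple[str, ...]
    ws: np.ndarray
    wp: np.ndarray
    wq: np.ndarray
    rank: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        alts = tuple(self.alternatives)
        m = len(alts)
        ws = np.asarray(self.ws, dtype=float)
        wp = np.asarray(self.wp, dtype=float)
        wq = np.asarray(self.wq, dtype=float)
        rank = np.asarray(self.rank, dtype=int)
        for name, a in (("ws", ws), ("wp", wp), ("wq", wq), ("rank", rank)):
            if a.shape != (m,):
                raise ShapeMismatchError(f"{name} shape {a.shape} != ({m},)")
        if not 0.0 <= self.lam <= 1.0:
            raise ValidationError(f"lambda must be in [0, 1], got {self.lam}")
        lo = np.minimum(ws, wp) - 1e-12
        hi = np.maximum(ws, wp) + 1e-12
        if np.any(wq < lo) or np.any(wq > hi):
            raise ValidationError("wq must lie between ws and wp")
        if np.any(rank < 1) or np.any(rank > m):
            raise ValidationError("ranks must lie in 1..m")
        for nm, a in (("alternatives", alts),):
            _check_unique(a, "alternative")
        for attr, a in (("ws", ws), ("wp", wp), ("wq", wq), ("rank", rank)):
            a.setflags(write=False)
            object.__setattr__(self, attr, a)
        object.__setattr__(self, "alternatives", alts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ScoreTable)
            and self.alternatives == other.alternatives
            and self.lam == other.lam
            and np.array_equal(self.rank, other.rank)
            and all(
                np.allclose(getattr(self, a), getattr(other, a), rtol=0, atol=1e-12)
                for a in ("ws", "wp", "wq")
            )
        )


@dataclass(frozen=True)
class RankVector:
    """A ranking of alternatives, tagged with the method that produced it."""

    alternatives: tuple[str, ...]
    ranks: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        alts = tuple(self.alternatives)
        _check_unique(alts, "alternative")
        r = np.asarray(self.ranks, dtype=int)
        if r.shape != (len(alts),):
            raise ShapeMismatchError("ranks length != alternatives length")
        if np.any(r < 1) or np.any(r > len(alts)):
            raise ValidationError("ranks must lie in 1..m")
        r.setflags(write=False)
        object.__setattr__(self, "alternatives", alts)
        object.__setattr__(self, "ranks", r)

    def __len__(self) -> int:
        return len(self.alternatives)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RankVector)
            and self.alternatives == other.alternatives
            and self.source == other.source
            and np.array_equal(self.ranks, other.ranks)
        )


@dataclass(frozen=True)
class GroupingResult:
    """Outcome of Lloyd's algorithm: labels, centers and diagnostics."""

    labels: np.ndarray
    centers: np.ndarray
    iterations: int
    inertia: float
    converged: bool
    initial_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        k = centers.shape[0]
        if np.any(labels < 0) or np.any(labels >= k):
            raise ValidationError("labels must lie in 0..k-1")
        if self.iterations < 0:
            raise ValidationError("iterations must be non-negative")
        if self.inertia < 0:
            raise ValidationError("inertia must be non-negative")
        labels.setflags(write=False)
        centers.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "centers", centers)
        if self.initial_centers is not None:
            ic = np.atleast_2d(np.asarray(self.initial_centers, dtype=float))
            ic.setflags(write=False)
            object.__setattr__(self, "initial_centers", ic)

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GroupingResult)
            and np.array_equal(self.labels, other.labels)
            and np.allclose(self.centers, other.centers, rtol=0, atol=1e-12)
            and self.iterations == other.iterations
            and abs(self.inertia - other.inertia) <= 1e-12 * max(1.0, self.inertia)
            and self.converged == other.converged
        )
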