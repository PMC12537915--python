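"""Aggregation: turn a normalized matrix and a weight vector into scores
and ranks.

WASPAS blends the weighted arithmetic sum WS_i = sum_j w_j x_ij and the
weighted geometric product WP_i = prod_j x_ij^{w_j}:

    WQ_i = lambda * WS_i + (1 - lambda) * WP_i,   lambda in [0, 1].

With positive values and weights summing to one, AM-GM gives
WP_i <= WS_i, so WQ is monotone non-decreasing in lambda. Ranks are
*competition* ranks on descending score (1 = best; ties share the
smallest rank, 1-2-2-4 style).

TOPSIS (closeness to the ideal / anti-ideal points of the weighted
matrix) and VIKOR (compromise Q from group utility S and individual
regret R) serve as external comparators in the robustness harness; both
consume the same normalized matrix as WASPAS so the aggregator is the
only varying factor.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array

from .datamodel import DecisionMatrix, RankVector, ScoreTable, WeightVector
from .errors import (
    DegenerateColumnError,
    IdenticalAlternativesError,
    ShapeMismatchError,
    UnknownMethodError,
    ValidationError,
)

__all__ = [
    "weighted_sum",
    "weighted_product",
    "waspas_score",
    "topsis_score",
    "vikor_score",
    "rank_alternatives",
    "WaspasScorer",
    "TopsisScorer",
    "VikorScorer",
    "AGGREGATION_METHODS",
]

AGGREGATION_METHODS = ("waspas", "topsis", "vikor")


def _values(X) -> np.ndarray:
    if isinstance(X, DecisionMatrix):
        return X.values
    return check_array(X, dtype=float, ensure_all_finite=True)


def _weights(w, n: int) -> np.ndarray:
    arr = w.weights if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if arr.shape != (n,):
        raise ShapeMismatchError(f"weights shape {arr.shape} != ({n},)")
    return arr


def _alternatives(X, m: int):
    if isinstance(X, DecisionMatrix):
        return X.alternatives
    return tuple(f"a{i+1}" for i in range(m))


def weighted_sum(X, w) -> np.ndarray:
    V = _values(X)
    return V @ _weights(w, V.shape[1])


def weighted_product(X, w, allow_zero: bool = False) -> np.ndarray:
    """Weighted geometric mean, computed in the log domain.

    Non-positive entries raise by default. ``allow_zero=True`` accepts
    exact zeros (e.g. the column minimum under min-max normalization) and
    evaluates the exact limit ``0^w = 0`` for positive weight; negatives
    always raise.
    """
    V = _values(X)
    bad = V < 0 if allow_zero else V <= 0
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"weighted product needs "
            f"{'non-negative' if allow_zero else 'strictly positive'} "
            f"values; found {V[i, j]!r} at row {i}, column {j}"
        )
    with np.errstate(divide="ignore"):
        logv = np.where(V > 0, np.log(np.where(V > 0, V, 1.0)), -np.inf)
    wts = _weights(w, V.shape[1])
    out = np.full(V.shape[0], -np.inf)
    finite = ~np.any((logv == -np.inf) & (wts > 0), axis=1)
    out[finite] = (np.where(wts > 0, logv, 0.0) * wts)[finite].sum(axis=1)
    return np.exp(out)


def rank_alternatives(scores, alternatives=None, higher_is_better: bool = True,
                      source: str = "") -> RankVector:
    """Competition ranking (1, 2, 2, 4) of the scores; 1 = best.

    The stored order of alternatives is preserved; ties share the same
    rank value, so the tiebreak only matters for presentation order.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    key = -s if higher_is_better else s
    ranks = rankdata(key, method="min").astype(int)
    if alternatives is None:
        alternatives = tuple(f"a{i+1}" for i in range(s.size))
    return RankVector(tuple(alternatives), ranks, source=source)


def waspas_score(X, w, lam: float = 0.5, allow_zero: bool = False) -> ScoreTable:
    """WASPAS score table: WQ = lam*WS + (1-lam)*WP, ranked descending."""
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must be in [0, 1], got {lam}")
    V = _values(X)
    ws = weighted_sum(V, _weights(w, V.shape[1]))
    wp = weighted_product(V, _weights(w, V.shape[1]), allow_zero=allow_zero)
    wq = lam * ws + (1.0 - lam) * wp
    ranks = rank_alternatives(wq).ranks
    return ScoreTable(_alternatives(X, V.shape[0]), ws, wp, wq, ranks, lam)


def topsis_score(X, w):
    """TOPSIS closeness coefficients and ranks (higher closeness = better).

    Directions are assumed already folded in by normalization, so the
    ideal point is the per-column max of the weighted matrix.
    """
    V = _values(X)
    W = V * _weights(w, V.shape[1])
    ideal = W.max(axis=0)
    anti = W.min(axis=0)
    if np.allclose(ideal, anti):
        raise IdenticalAlternativesError(
            "all alternatives identical; TOPSIS closeness undefined"
        )
    d_pos = np.linalg.norm(W - ideal, axis=1)
    d_neg = np.linalg.norm(W - anti, axis=1)
    closeness = d_neg / (d_pos + d_neg)
    return closeness, rank_alternatives(
        closeness, _alternatives(X, V.shape[0]), source="topsis"
    )


def vikor_score(X, w, v: float = 0.5):
    """VIKOR compromise index Q (lower = better) and ranks.

    S_i (group utility) and R_i (individual regret) use the weighted
    normalized gaps to the per-criterion best; Q blends them with weight
    ``v``. A degenerate spread (S* = S^- or R* = R^-) zeroes that term.
    """
    if not 0.0 <= v <= 1.0:
        raise ValidationError(f"v must be in [0, 1], got {v}")
    V = _values(X)
    wts = _weights(w, V.shape[1])
    f_best = V.max(axis=0)
    f_worst = V.min(axis=0)
    spread = f_best - f_worst
    if np.any(spread == 0):
        j = int(np.argmin(spread))
        raise DegenerateColumnError(f"criterion {j} is constant across alternatives")
    gaps = wts * (f_best - V) / spread
    S = gaps.sum(axis=1)
    R = gaps.max(axis=1)
    Q = np.zeros(V.shape[0])
    for comp, weight in ((S, v), (R, 1.0 - v)):
        lo, hi = comp.min(), comp.max()
        if hi > lo:
            Q += weight * (comp - lo) / (hi - lo)
    return Q, rank_alternatives(
        Q, _alternatives(X, V.shape[0]), higher_is_better=False, source="vikor"
    )


class WaspasScorer(BaseEstimator):
    """WASPAS as an estimator: fit sets ``ws_``, ``wp_``, ``scores_``,
    ``ranks_`` and ``score_table_``.

    Parameters
    ----------
    weights : array-like or WeightVector or None
        Criterion weights; None means equal weights.
    lam : float in [0, 1]
        Blend between weighted sum (1) and weighted product (0).
    """

    def __init__(self, weights=None, lam=0.5):
        self.weights = weights
        self.lam = lam

    def _w(self, n):
        if self.weights is None:
            return np.full(n, 1.0 / n)
        return _weights(self.weights, n)

    def fit(self, X, y=None):
        V = _values(X)
        st = waspas_score(X, self._w(V.shape[1]), self.lam)
        self.ws_ = st.ws
        self.wp_ = st.wp
        self.scores_ = st.wq
        self.ranks_ = st.rank
        self.score_table_ = st
        self.n_features_in_ = V.shape[1]
        return self

    def fit_predict(self, X, y=None):
        """Return the rank of each alternative (1 = best)."""
        return self.fit(X, y).ranks_


class TopsisScorer(BaseEstimator):
    def __init__(self, weights=None):
        self.weights = weights

    def fit(self, X, y=None):
        V = _values(X)
        w = (np.full(V.shape[1], 1.0 / V.shape[1])
             if self.weights is None else _weights(self.weights, V.shape[1]))
        self.scores_, rv = topsis_score(X, w)
        self.ranks_ = rv.ranks
        self.n_features_in_ = V.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).ranks_


class VikorScorer(BaseEstimator):
    def __init__(self, weights=None, v=0.5):
        self.weights = weights
        self.v = v

    def fit(self, X, y=None):
        V = _values(X)
        w = (np.full(V.shape[1], 1.0 / V.shape[1])
             if self.weights is None else _weights(self.weights, V.shape[1]))
        self.scores_, rv = vikor_score(X, w, self.v)
        self.ranks_ = rv.ranks
        self.n_features_in_ = V.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).ranks_


def aggregate(X, w, method: str, lam: float = 0.5, vikor_v: float = 0.5,
              allow_zero: bool = False):
    """Dispatch: return (scores, RankVector) for the named aggregator.

    For WASPAS the scores are WQ and the RankVector is drawn from the
    ScoreTable.
    """
    if method == "waspas":
        st = waspas_score(X, w, lam, allow_zero=allow_zero)
        return st.wq, RankVector(st.alternatives, st.rank, source="waspas")
    if method == "topsis":
        return topsis_score(X, w)
    if method == "vikor":
        return vikor_score(X, w, vikor_v)
    raise UnknownMethodError(
        f"unknown aggregation {method!r}; known: {', '.join(AGGREGATION_METHODS)}"
    )
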