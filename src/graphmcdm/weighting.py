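"""Objective criterion weighting.

The model's weigher is DCRITIC: CRITIC with Pearson correlation replaced
by *distance correlation* (dCor). For each criterion j,

    I_j = t_j * sum_{j'} (1 - dCor(o_j, o_j')),      w_j = I_j / sum_j I_j

where ``t_j`` is the sample standard deviation of the normalized column
(ddof = 1) and the sum runs over all j' including j' = j (whose term is 0
for non-constant columns). A criterion thus earns weight by carrying
contrast (large t_j) *and* by being non-redundant with the others (small
dCor). dCor uses the classical Szekely-Rizzo V-statistic with
double-centered distance matrices; dCor against a constant column is
defined as 0 (that column's t_j is 0 anyway, avoiding 0/0).

Entropy and MEREC weighting are included as robustness comparators.
All three are exposed both as scikit-learn style estimators (``fit`` sets
``weights_``) and as functions returning a WeightVector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .datamodel import DecisionMatrix, WeightVector
from .errors import (
    DegenerateWeightsError,
    ShapeMismatchError,
    ValidationError,
)

__all__ = [
    "CriterionStats",
    "column_sd",
    "distance_correlation",
    "information_content",
    "dcritic_weights",
    "entropy_weights",
    "merec_weights",
    "compute_weights",
    "DCRITICWeigher",
    "EntropyWeigher",
    "MERECWeigher",
    "WEIGHTING_METHODS",
]

WEIGHTING_METHODS = ("dcritic", "entropy", "merec")


@dataclass(frozen=True)
class CriterionStats:
    """Intermediate DCRITIC quantities: sds, dCor matrix, information."""

    sd: np.ndarray          # t_j, length n
    dcor: np.ndarray        # n x n, symmetric, unit diagonal (non-constant cols)
    information: np.ndarray  # I_j, length n


def _values(X) -> np.ndarray:
    if isinstance(X, DecisionMatrix):
        return X.values
    return check_array(X, dtype=float, ensure_all_finite=True)


def column_sd(X) -> np.ndarray:
    """Sample standard deviation (ddof=1) of each criterion column."""
    V = _values(X)
    if V.shape[0] < 2:
        raise ValidationError("need at least 2 alternatives for a sd")
    return V.std(axis=0, ddof=1)


def _centered_distances(u: np.ndarray) -> np.ndarray:
    a = np.abs(u[:, None] - u[None, :])
    return a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()


def distance_correlation(u, v) -> float:
    """Szekely-Rizzo distance correlation (V-statistic) of two sequences.

    Returns 0 when either sequence has zero distance variance (constant).
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ShapeMismatchError(f"length mismatch: {u.size} vs {v.size}")
    if u.size < 2:
        raise ValidationError("need at least 2 observations")
    A = _centered_distances(u)
    B = _centered_distances(v)
    m2 = u.size ** 2
    dcov2 = (A * B).sum() / m2
    dvar_u = (A * A).sum() / m2
    dvar_v = (B * B).sum() / m2
    if dvar_u <= 0 or dvar_v <= 0:
        return 0.0
    # clip: dcov2 is non-negative in exact arithmetic but can dip below 0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_u * dvar_v)))


def _dcor_matrix(V: np.ndarray) -> np.ndarray:
    n = V.shape[1]
    A = [_centered_distances(V[:, j]) for j in range(n)]
    m2 = V.shape[0] ** 2
    dvar = np.array([(Aj * Aj).sum() / m2 for Aj in A])
    DC = np.zeros((n, n))
    for j in range(n):
        for jp in range(j, n):
            if dvar[j] <= 0 or dvar[jp] <= 0:
                val = 0.0
            else:
                dcov2 = (A[j] * A[jp]).sum() / m2
                val = float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar[j] * dvar[jp])))
            DC[j, jp] = DC[jp, j] = min(val, 1.0)
    return DC


def information_content(sd, dcor) -> np.ndarray:
    """I_j = t_j * sum_j' (1 - dCor_jj'), self term included (it is 0)."""
    sd = np.asarray(sd, dtype=float)
    DC = np.asarray(dcor, dtype=float)
    if DC.shape != (sd.size, sd.size):
        raise ShapeMismatchError(f"dcor shape {DC.shape} != ({sd.size}, {sd.size})")
    return sd * (1.0 - DC).sum(axis=1)


def criterion_stats(X) -> CriterionStats:
    V = _values(X)
    sd = column_sd(V)
    DC = _dcor_matrix(V)
    return CriterionStats(sd, DC, information_content(sd, DC))


def _as_weight_vector(w: np.ndarray, method: str, X) -> WeightVector:
    ids = X.criterion_ids if isinstance(X, DecisionMatrix) else None
    return WeightVector(w, method, ids)


def dcritic_weights(X) -> WeightVector:
    """Distance-correlation CRITIC weights of the (normalized) columns."""
    V = _values(X)
    if V.shape[1] < 2:
        raise ValidationError("DCRITIC needs at least 2 criteria")
    stats = criterion_stats(V)
    total = stats.information.sum()
    if total <= 0:
        raise DegenerateWeightsError(
            "all criteria carry zero information content (columns mutually "
            "affine or constant); DCRITIC weights are undefined"
        )
    return _as_weight_vector(stats.information / total, "dcritic", X)


def entropy_weights(X) -> WeightVector:
    """Shannon-entropy weights: w_j proportional to 1 - e_j."""
    V = _values(X)
    if np.any(V < 0):
        raise ValidationError("entropy weighting needs non-negative values")
    colsum = V.sum(axis=0)
    if np.any(colsum <= 0):
        raise DegenerateWeightsError("zero-sum column in entropy weighting")
    P = V / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    e = -plogp.sum(axis=0) / np.log(V.shape[0])
    d = 1.0 - e
    d = np.clip(d, 0.0, None)  # e can exceed 1 by rounding on uniform columns
    if d.sum() <= 0:
        raise DegenerateWeightsError(
            "every column has maximal entropy; weights undefined"
        )
    return _as_weight_vector(d / d.sum(), "entropy", X)


def merec_weights(X, uniform_fallback: bool = False) -> WeightVector:
    """MEREC: weight by the effect of removing each criterion.

    S_i = ln(1 + mean_j |ln x_ij|); S'_ij omits criterion j;
    E_j = sum_i |S'_ij - S_i|; w_j = E_j / sum E. Requires values in (0, 1].
    """
    V = _values(X)
    if np.any(V <= 0):
        raise ValidationError("MEREC needs strictly positive values")
    m, n = V.shape
    absln = np.abs(np.log(V))
    total = absln.sum(axis=1)
    S = np.log(1.0 + total / n)
    # S'_ij: remove column j from the inner mean (divisor stays n, per the
    # canonical formulation)
    Sp = np.log(1.0 + (total[:, None] - absln) / n)
    E = np.abs(Sp - S[:, None]).sum(axis=0)
    if E.sum() <= 0:
        if uniform_fallback:
            return _as_weight_vector(np.full(n, 1.0 / n), "merec", X)
        raise DegenerateWeightsError(
            "no criterion has a removal effect (all values 1?); "
            "pass uniform_fallback=True for equal weights"
        )
    return _as_weight_vector(E / E.sum(), "merec", X)


def compute_weights(X, method: str, **kwargs) -> WeightVector:
    """Dispatch to the named weighting method."""
    from .errors import UnknownMethodError

    fns = {
        "dcritic": dcritic_weights,
        "entropy": entropy_weights,
        "merec": merec_weights,
    }
    if method not in fns:
        raise UnknownMethodError(
            f"unknown weighting {method!r}; known: {', '.join(WEIGHTING_METHODS)}"
        )
    return fns[method](X, **kwargs)


class _Weigher(BaseEstimator):
    """Fit computes ``weights_`` from the columns of X."""

    _method: str

    def fit(self, X, y=None):
        wv = compute_weights(_values(X), self._method, **self._fit_kwargs())
        self.weights_ = wv.weights
        self.n_features_in_ = self.weights_.size
        return self

    def _fit_kwargs(self):
        return {}

    def fit_transform(self, X, y=None):
        """Return the weighted matrix (columns scaled by their weights)."""
        self.fit(X, y)
        return _values(X) * self.weights_

    def transform(self, X):
        check_is_fitted(self, "weights_")
        return _values(X) * self.weights_


class DCRITICWeigher(_Weigher):
    """Distance-correlation CRITIC objective weighting.

    Fitted attributes: ``weights_`` plus the intermediate ``sd_``,
    ``dcor_`` and ``information_``.
    """

    _method = "dcritic"

    def fit(self, X, y=None):
        V = _values(X)
        stats = criterion_stats(V)
        self.sd_ = stats.sd
        self.dcor_ = stats.dcor
        self.information_ = stats.information
        wv = dcritic_weights(V)
        self.weights_ = wv.weights
        self.n_features_in_ = self.weights_.size
        return self


class EntropyWeigher(_Weigher):
    _method = "entropy"


class MERECWeigher(_Weigher):
    def __init__(self, uniform_fallback=False):
        self.uniform_fallback = uniform_fallback

    _method = "merec"

    def _fit_kwargs(self):
        return {"uniform_fallback": self.uniform_fallback}
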