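"""Normalization: map raw criterion columns onto a common scale.

The model's own normalizer is a *logistic* (sigmoid) map: benefit criteria
use ``1 / (1 + exp(-x))`` (increasing), cost criteria the decreasing form
``1 / (1 + exp(x))``. Because raw indicators can differ by orders of
magnitude (a GDP next to a percentage saturates the sigmoid), columns are
z-scored first by default (``standardize_first=True``); a
``strict_verbatim`` switch applies the decreasing form to every column
regardless of direction, for auditing the published formula as printed.

Three classical alternatives are provided for the robustness harness:

* fuzzy quantization — linear (triangular) min-max membership,
  ``(x - min) / (max - min)`` for benefit, reversed for cost;
* decimal scaling — divide each column by the smallest power of ten that
  brings ``max |x|`` to at most 1; cost columns are then flipped
  ``1 - value``;
* vector — divide each column by its Euclidean norm; cost columns flipped
  ``1 - value``.

All normalizers are scikit-learn transformers (fit learns the per-column
statistics, transform applies them); the module-level functions wrap them
for :class:`~graphmcdm.datamodel.DecisionMatrix` in / out use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datamodel import BENEFIT, COST, DecisionMatrix, NormalizedMatrix
from .errors import DegenerateColumnError, UnknownMethodError

__all__ = [
    "LogisticNormalizer",
    "FuzzyQuantizationNormalizer",
    "DecimalScalingNormalizer",
    "VectorNormalizer",
    "normalize",
    "normalize_logistic",
    "normalize_fuzzy_quantization",
    "normalize_decimal_scaling",
    "normalize_vector",
    "METHOD_ALIASES",
]

METHOD_ALIASES = {
    "logistic": "logistic",
    "fq": "fuzzy_quantization",
    "fuzzy_quantization": "fuzzy_quantization",
    "ds": "decimal_scaling",
    "decimal_scaling": "decimal_scaling",
    "ve": "vector",
    "vector": "vector",
}


def _signs(directions, n: int) -> np.ndarray:
    """+1 for benefit, -1 for cost; directions may be None (all benefit)."""
    if directions is None:
        return np.ones(n)
    dirs = list(directions)
    if len(dirs) != n:
        raise DegenerateColumnError(
            f"got {len(dirs)} directions for {n} columns"
        )
    out = np.empty(n)
    for j, d in enumerate(dirs):
        if d in (BENEFIT, 1, +1):
            out[j] = 1.0
        elif d in (COST, -1):
            out[j] = -1.0
        else:
            raise UnknownMethodError(f"bad direction {d!r}")
    return out


class _DirectedNormalizer(TransformerMixin, BaseEstimator):
    """Shared plumbing: direction handling and 2-D float validation."""

    method: str

    def __init__(self, directions=None):
        self.directions = directions

    def _validate(self, X, reset):
        X = check_array(X, dtype=float, ensure_all_finite=True)
        if reset:
            self.n_features_in_ = X.shape[1]
            self.signs_ = _signs(self.directions, X.shape[1])
        elif X.shape[1] != self.n_features_in_:
            raise DegenerateColumnError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        return X

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y, **kw).transform(X)


class LogisticNormalizer(_DirectedNormalizer):
    """Sigmoid normalizer with optional per-column z-scoring.

    Parameters
    ----------
    directions : sequence of {"benefit", "cost"} or None
        Orientation per column; None means all benefit.
    standardize_first : bool, default True
        Z-score each column (mean 0, sd 1, ddof=1) before the sigmoid.
        Zero-variance columns then raise DegenerateColumnError.
    strict_verbatim : bool, default False
        Apply the decreasing sigmoid ``1/(1+e^x)`` to *every* column,
        ignoring directions (the published formula as printed).
    """

    method = "logistic"

    def __init__(self, directions=None, standardize_first=True,
                 strict_verbatim=False):
        super().__init__(directions)
        self.standardize_first = standardize_first
        self.strict_verbatim = strict_verbatim

    def fit(self, X, y=None):
        X = self._validate(X, reset=True)
        if self.standardize_first:
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0, ddof=1)
            if np.any(self.scale_ == 0):
                j = int(np.argmin(self.scale_))
                raise DegenerateColumnError(
                    f"column {j} has zero variance; cannot z-score"
                )
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = self._validate(X, reset=False)
        Z = (X - self.mean_) / self.scale_
        sign = -np.ones_like(self.signs_) if self.strict_verbatim else self.signs_
        # benefit: 1/(1+e^-z) increasing; cost: 1/(1+e^z) decreasing
        from scipy.special import expit

        return expit(Z * sign)


class FuzzyQuantizationNormalizer(_DirectedNormalizer):
    """Linear min-max membership; benefit ``(x-min)/range``, cost reversed."""

    method = "fuzzy_quantization"

    def fit(self, X, y=None):
        X = self._validate(X, reset=True)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        if np.any(self.data_max_ == self.data_min_):
            j = int(np.argmin(self.data_max_ - self.data_min_))
            raise DegenerateColumnError(f"column {j} is constant")
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = self._validate(X, reset=False)
        up = (X - self.data_min_) / (self.data_max_ - self.data_min_)
        down = (self.data_max_ - X) / (self.data_max_ - self.data_min_)
        return np.where(self.signs_ > 0, up, down)


class DecimalScalingNormalizer(_DirectedNormalizer):
    """Divide each column by 10^d, the smallest d with ``max|x| <= 10^d``.

    All-zero columns pass through unchanged (d = 0). Cost columns are
    flipped ``1 - value`` after scaling.
    """

    method = "decimal_scaling"

    def fit(self, X, y=None):
        X = self._validate(X, reset=True)
        amax = np.abs(X).max(axis=0)
        d = np.zeros(X.shape[1], dtype=int)
        nz = amax > 0
        d[nz] = np.ceil(np.log10(amax[nz]))
        # guard rounding: enforce the defining inequality max|x|/10^d <= 1
        for j in np.flatnonzero(nz):
            while amax[j] / 10.0 ** d[j] > 1:
                d[j] += 1
            while d[j] > 0 and amax[j] / 10.0 ** (d[j] - 1) <= 1:
                d[j] -= 1
        self.digits_ = d
        self.scale_ = 10.0 ** d
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = self._validate(X, reset=False)
        V = X / self.scale_
        return np.where(self.signs_ > 0, V, 1.0 - V)


class VectorNormalizer(_DirectedNormalizer):
    """Divide each column by its Euclidean norm; cost columns flipped."""

    method = "vector"

    def fit(self, X, y=None):
        X = self._validate(X, reset=True)
        self.norm_ = np.linalg.norm(X, axis=0)
        if np.any(self.norm_ == 0):
            j = int(np.argmin(self.norm_))
            raise DegenerateColumnError(f"column {j} is all zero")
        return self

    def transform(self, X):
        check_is_fitted(self, "norm_")
        X = self._validate(X, reset=False)
        V = X / self.norm_
        return np.where(self.signs_ > 0, V, 1.0 - V)


_NORMALIZERS = {
    "logistic": LogisticNormalizer,
    "fuzzy_quantization": FuzzyQuantizationNormalizer,
    "decimal_scaling": DecimalScalingNormalizer,
    "vector": VectorNormalizer,
}


def _wrap(X: DecisionMatrix, values: np.ndarray, method: str) -> NormalizedMatrix:
    return NormalizedMatrix(X.alternatives, X.criteria, values, method)


def normalize_logistic(X: DecisionMatrix, standardize_first: bool = True,
                       strict_verbatim: bool = False) -> NormalizedMatrix:
    est = LogisticNormalizer(X.directions, standardize_first, strict_verbatim)
    return _wrap(X, est.fit_transform(X.values), "logistic")


def normalize_fuzzy_quantization(X: DecisionMatrix) -> NormalizedMatrix:
    est = FuzzyQuantizationNormalizer(X.directions)
    return _wrap(X, est.fit_transform(X.values), "fuzzy_quantization")


def normalize_decimal_scaling(X: DecisionMatrix) -> NormalizedMatrix:
    est = DecimalScalingNormalizer(X.directions)
    return _wrap(X, est.fit_transform(X.values), "decimal_scaling")


def normalize_vector(X: DecisionMatrix) -> NormalizedMatrix:
    est = VectorNormalizer(X.directions)
    return _wrap(X, est.fit_transform(X.values), "vector")


def normalize(X: DecisionMatrix, method: str, **kwargs) -> NormalizedMatrix:
    """Dispatch to the named normalizer (aliases fq/ds/ve accepted)."""
    try:
        canonical = METHOD_ALIASES[method]
    except KeyError:
        raise UnknownMethodError(
            f"unknown normalization {method!r}; known: "
            + ", ".join(sorted(set(METHOD_ALIASES)))
        ) from None
    fn = {
        "logistic": normalize_logistic,
        "fuzzy_quantization": normalize_fuzzy_quantization,
        "decimal_scaling": normalize_decimal_scaling,
        "vector": normalize_vector,
    }[canonical]
    return fn(X, **kwargs)
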