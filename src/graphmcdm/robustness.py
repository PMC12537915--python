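"""Robustness protocol and score analytics.

The robustness harness re-runs the scoring pipeline while varying exactly
one factor (normalization, weighting or aggregation), then quantifies
agreement between variants two ways: Spearman's rho between the rank
vectors (tie-corrected, i.e. Pearson correlation of rank values) and the
V-measure between the k-means groupings (entropy-based, permutation
invariant, beta = 1).

Two analytics support interpretation of the composite score:

* score deconstruction: the additive contribution ``w_j * x_ij`` of each
  criterion to each alternative's weighted sum WS_i;
* change decomposition: between two time points with one weight vector,
  ``w_j * (x_ij(t2) - x_ij(t1))``, which sums exactly to the change in
  WS_i and classifies each criterion as contributing / regressing /
  neutral.

Both use the weighted-sum convention because it is the one that is exact:
WQ mixes WS and WP and is not additive in the criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .aggregate import aggregate, weighted_sum
from .cluster import cluster_graph_kmeans, lloyd, baseline_init
from .datamodel import DecisionMatrix, RankVector, WeightVector
from .errors import ShapeMismatchError, UnknownMethodError, ValidationError
from .normalize import METHOD_ALIASES, normalize
from .weighting import compute_weights

__all__ = [
    "ComparisonReport",
    "DecompositionTable",
    "spearman_rho",
    "vmeasure",
    "robustness_matrix",
    "rank_agreement_matrix",
    "group_agreement_matrix",
    "score_deconstruction",
    "change_decomposition",
    "init_benchmark",
]


@dataclass(frozen=True)
class ComparisonReport:
    """Pairwise agreement between pipeline variants."""

    variants: tuple[str, ...]
    rho: np.ndarray                      # Spearman between rank vectors
    vmeasure: np.ndarray | None = None   # between groupings, if clustered
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DecompositionTable:
    """Per alternative x criterion contributions; rows sum to the totals."""

    contributions: pd.DataFrame   # index = alternatives, columns = criteria
    totals: pd.Series             # WS_i (or delta WS_i)
    classification: pd.DataFrame | None = None  # contributing/regressing/neutral


# ------------------------------------------------------------- statistics

def spearman_rho(r1, r2) -> float:
    """Tie-corrected Spearman: Pearson correlation of the rank values."""
    a = r1.ranks if isinstance(r1, RankVector) else np.asarray(r1, dtype=float)
    b = r2.ranks if isinstance(r2, RankVector) else np.asarray(r2, dtype=float)
    if isinstance(r1, RankVector) and isinstance(r2, RankVector):
        if r1.alternatives != r2.alternatives:
            raise ShapeMismatchError("rank vectors cover different alternatives")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ShapeMismatchError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValidationError("need at least 2 items")
    ra = rankdata(a)
    rb = rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(ra, rb)[0, 1])


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def vmeasure(labels_a, labels_b) -> float:
    """V-measure (beta = 1): harmonic mean of homogeneity and completeness.

    Computed from the contingency table with natural-log entropies;
    invariant to label permutation. Conventions: a conditional-entropy
    ratio with zero denominator counts as 0 (i.e. h or c = 1), and V = 0
    when h + c = 0.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ShapeMismatchError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValidationError("empty labelings")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    cont = np.zeros((ka, kb))
    np.add.at(cont, (ai, bi), 1.0)
    n = a.size
    h_a = _entropy(cont.sum(axis=1))
    h_b = _entropy(cont.sum(axis=0))
    # H(A|B) = sum_b p(b) H(A | B=b)
    h_a_given_b = sum(
        (cont[:, j].sum() / n) * _entropy(cont[:, j]) for j in range(kb)
    )
    h_b_given_a = sum(
        (cont[i].sum() / n) * _entropy(cont[i]) for i in range(ka)
    )
    h = 1.0 if h_a == 0 else 1.0 - h_a_given_b / h_a
    c = 1.0 if h_b == 0 else 1.0 - h_b_given_a / h_b
    if h + c == 0:
        return 0.0
    return float(2.0 * h * c / (h + c))


# -------------------------------------------------------------- harness

_VARIANTS = {
    "normalization": ("logistic", "fuzzy_quantization", "decimal_scaling", "vector"),
    "weighting": ("dcritic", "entropy", "merec"),
    "aggregation": ("waspas", "topsis", "vikor"),
}


def _run_variant(X: DecisionMatrix, normalization, weighting, aggregation,
                 lam, vikor_v, k, sigma):
    N = normalize(X, normalization)
    w = compute_weights(N, weighting)
    # min-max normalization puts the column minimum at exactly 0; the
    # weighted product takes its exact limit 0^w = 0 there
    scores, rv = aggregate(N, w, aggregation, lam=lam, vikor_v=vikor_v,
                           allow_zero=True)
    labels = None
    if k is not None:
        merit = scores if aggregation != "vikor" else -scores
        labels = cluster_graph_kmeans(merit[:, None], k, sigma).labels
    return rv, labels


def rank_agreement_matrix(rank_vectors) -> np.ndarray:
    n = len(rank_vectors)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = spearman_rho(rank_vectors[i], rank_vectors[j])
    return M


def group_agreement_matrix(labelings) -> np.ndarray:
    n = len(labelings)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = vmeasure(labelings[i], labelings[j])
    return M


def robustness_matrix(X: DecisionMatrix, vary: str, normalization="logistic",
                      weighting="dcritic", aggregation="waspas", lam=0.5,
                      vikor_v=0.5, k=None, sigma="auto",
                      variants=None) -> ComparisonReport:
    """Run the pipeline once per variant of one factor; report agreement.

    ``k=None`` skips clustering (the V-measure matrix is then None).
    """
    if vary not in _VARIANTS:
        raise UnknownMethodError(
            f"vary must be one of {', '.join(_VARIANTS)}; got {vary!r}"
        )
    names = tuple(variants) if variants is not None else _VARIANTS[vary]
    if vary == "normalization":
        bad = [v for v in names if v not in METHOD_ALIASES]
        if bad:
            raise UnknownMethodError(f"unknown normalization variants: {bad}")
    fixed = dict(normalization=normalization, weighting=weighting,
                 aggregation=aggregation)
    rvs, labelings = [], []
    for name in names:
        cfg = dict(fixed)
        cfg[vary] = name
        rv, labels = _run_variant(X, cfg["normalization"], cfg["weighting"],
                                  cfg["aggregation"], lam, vikor_v, k, sigma)
        rvs.append(rv)
        labelings.append(labels)
    rho = rank_agreement_matrix(rvs)
    vm = group_agreement_matrix(labelings) if k is not None else None
    return ComparisonReport(
        names, rho, vm,
        meta={"vary": vary, **fixed, "lambda": lam, "vikor_v": vikor_v,
              "k": k, "sigma": sigma},
    )


# ------------------------------------------------------------ analytics

def _frame(X, w):
    if isinstance(X, DecisionMatrix):
        V, alts, crits = X.values, list(X.alternatives), list(X.criterion_ids)
    else:
        V = np.asarray(X, dtype=float)
        alts = [f"a{i+1}" for i in range(V.shape[0])]
        crits = [f"c{j+1}" for j in range(V.shape[1])]
    wts = w.weights if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if wts.shape != (V.shape[1],):
        raise ShapeMismatchError(
            f"weights shape {wts.shape} != ({V.shape[1]},)"
        )
    return V, wts, alts, crits


def score_deconstruction(X, w) -> DecompositionTable:
    """Additive contribution w_j * x_ij of every criterion to WS_i."""
    V, wts, alts, crits = _frame(X, w)
    contrib = pd.DataFrame(V * wts, index=alts, columns=crits)
    totals = pd.Series(weighted_sum(V, wts), index=alts, name="ws")
    return DecompositionTable(contrib, totals)


def change_decomposition(X_t1, X_t2, w, tol: float = 1e-12) -> DecompositionTable:
    """Per-cell contribution to the change in WS between two time points.

    Uses a single weight vector so the decomposition is exactly additive;
    classifies each cell as contributing (+), regressing (-) or neutral
    (|delta contribution| < ``tol``).
    """
    if isinstance(X_t1, DecisionMatrix) and isinstance(X_t2, DecisionMatrix):
        if (X_t1.alternatives != X_t2.alternatives
                or X_t1.criterion_ids != X_t2.criterion_ids):
            raise ShapeMismatchError(
                "the two time points cover different alternatives/criteria"
            )
    V1, wts, alts, crits = _frame(X_t1, w)
    V2, _, _, _ = _frame(X_t2, w)
    if V1.shape != V2.shape:
        raise ShapeMismatchError(f"shape mismatch: {V1.shape} vs {V2.shape}")
    delta = pd.DataFrame((V2 - V1) * wts, index=alts, columns=crits)
    totals = pd.Series(weighted_sum(V2, wts) - weighted_sum(V1, wts),
                       index=alts, name="delta_ws")
    cls = pd.DataFrame(
        np.where(np.abs(delta.to_numpy()) < tol, "neutral",
                 np.where(delta.to_numpy() > 0, "contributing", "regressing")),
        index=alts, columns=crits,
    )
    return DecompositionTable(delta, totals, cls)


# ------------------------------------------------------------ benchmark

def init_benchmark(datasets, k: int, inits=("graph", "random"),
                   repeats: int = 20, seed: int = 0, sigma="auto") -> pd.DataFrame:
    """Compare seeding strategies on iteration count and stability.

    ``datasets`` is a sequence of (id, points) pairs. For each dataset and
    strategy the benchmark records Lloyd iterations, final inertia, and
    the number of distinct label partitions over ``repeats`` seeded runs
    (1 = fully stable). Deterministic strategies are run ``repeats`` times
    too, which doubles as a determinism check.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for ds_id, pts in datasets:
        pts = np.asarray(pts, dtype=float)
        for init in inits:
            partitions = set()
            iters, inertias = [], []
            child_seeds = ss.spawn(repeats)
            for r in range(repeats):
                if init == "graph":
                    res = cluster_graph_kmeans(pts, k, sigma)
                else:
                    rng_seed = child_seeds[r]
                    C0 = baseline_init(pts, k, init,
                                       np.random.default_rng(rng_seed))
                    res = lloyd(pts, C0)
                # canonical form: relabel by first occurrence
                _, canon = np.unique(res.labels, return_inverse=True)
                first = {}
                canonical = []
                for lab in res.labels:
                    if lab not in first:
                        first[lab] = len(first)
                    canonical.append(first[lab])
                partitions.add(tuple(canonical))
                iters.append(res.iterations)
                inertias.append(res.inertia)
            rows.append({
                "dataset_id": ds_id,
                "init": init,
                "iterations": float(np.median(iters)),
                "inertia": float(np.median(inertias)),
                "distinct_partitions": len(partitions),
                "stable": len(partitions) == 1,
            })
    return pd.DataFrame(rows)
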