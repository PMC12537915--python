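"""Graph-seeded k-means.

Plain Lloyd iterations are sensitive to the initial centers: different
random seeds can land in different local optima. The method implemented
here removes that randomness by seeding from the spectrum of a similarity
graph over the points:

1. Gaussian similarity  S_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)),
   with sigma defaulting to the median pairwise Euclidean distance;
2. unnormalized graph Laplacian  L = D - S  with degrees D_ii = sum_j S_ij
   (the self term cancels in D - S, so including it is harmless);
3. spectral embedding U: the eigenvectors of the k smallest eigenvalues
   of L (ascending), with a deterministic sign convention;
4. a deterministic k-means on the rows of U (farthest-first seeding) whose
   *assignment* is transferred back: each initial center is the mean of
   the original-space points in one embedded cluster;
5. Lloyd iterations in the original space from those centers.

Every step is deterministic given (points, k, sigma), so repeated runs
produce bit-identical labels. Classical seedings (random, k-means++,
farthest-first) are provided for benchmarking iteration counts and
run-to-run stability against the spectral seeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datamodel import GroupingResult
from .errors import (
    IdenticalAlternativesError,
    UnknownMethodError,
    ValidationError,
)

__all__ = [
    "SimilarityGraph",
    "LaplacianPair",
    "SpectralEmbedding",
    "similarity_matrix",
    "laplacian",
    "spectral_embedding",
    "initial_centers",
    "lloyd",
    "cluster_graph_kmeans",
    "baseline_init",
    "GraphKMeans",
    "INIT_STRATEGIES",
]

INIT_STRATEGIES = ("graph", "random", "kmeanspp", "farthest_first")


@dataclass(frozen=True)
class SimilarityGraph:
    S: np.ndarray
    sigma: float
    dim: int


@dataclass(frozen=True)
class LaplacianPair:
    D: np.ndarray
    L: np.ndarray


@dataclass(frozen=True)
class SpectralEmbedding:
    U: np.ndarray            # m x k, columns ascending by eigenvalue
    eigenvalues: np.ndarray  # length k


def _points(X) -> np.ndarray:
    X = check_array(np.asarray(X, dtype=float), ensure_2d=False,
                    ensure_all_finite=True)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    return X


def similarity_matrix(points, sigma="auto", n_clusters=None) -> SimilarityGraph:
    """Gaussian similarity graph over the points.

    ``sigma="auto"`` picks a scale from the data. Without ``n_clusters``
    it is the median of the m(m-1)/2 pairwise Euclidean distances. When
    the intended number of groups k is known, the bandwidth should match
    the *within-group* scale rather than the global spread (the global
    median is far too wide once groups are well separated, and a graph
    that wide blurs them together), so auto-sigma becomes the median over
    points of the distance to their ceil(m/k)-th nearest neighbor — the
    expected neighborhood radius of a balanced group. Either way a zero
    scale falls back to the mean of the positive distances, and all points
    coinciding is an error.
    """
    X = _points(points)
    d = pdist(X)
    if sigma == "auto":
        if n_clusters is not None and n_clusters >= 1:
            # a balanced group has ceil(m/k) members, so its farthest
            # within-group neighbor is the (ceil(m/k)-1)-th nearest
            D = squareform(d)
            kth = int(np.ceil(X.shape[0] / n_clusters)) - 1
            kth = min(max(kth, 1), X.shape[0] - 1)
            sigma = float(np.median(np.sort(D, axis=1)[:, kth]))
        else:
            sigma = float(np.median(d))
        if sigma <= 0:
            pos = d[d > 0]
            if pos.size == 0:
                raise IdenticalAlternativesError(
                    "all points identical; auto sigma undefined"
                )
            sigma = float(pos.mean())
    else:
        sigma = float(sigma)
        if sigma <= 0:
            raise ValidationError(f"sigma must be positive, got {sigma}")
    S = np.exp(-squareform(d) ** 2 / (2.0 * sigma**2))
    np.fill_diagonal(S, 1.0)
    return SimilarityGraph(S, sigma, X.shape[1])


def laplacian(G: SimilarityGraph | np.ndarray) -> LaplacianPair:
    """Unnormalized Laplacian L = D - S; rows of L sum to zero."""
    S = G.S if isinstance(G, SimilarityGraph) else np.asarray(G, dtype=float)
    D = np.diag(S.sum(axis=1))
    return LaplacianPair(D, D - S)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (ties: first)."""
    U = U.copy()
    for c in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, c])))
        if U[i, c] < 0:
            U[:, c] = -U[:, c]
    return U


def spectral_embedding(LP: LaplacianPair | np.ndarray, k: int) -> SpectralEmbedding:
    """Eigenvectors of the k smallest eigenvalues of L, ascending.

    ``numpy.linalg.eigh`` returns ascending eigenvalues with a fixed
    deterministic ordering; signs are normalized so each column's entry of
    largest magnitude is positive.
    """
    L = LP.L if isinstance(LP, LaplacianPair) else np.asarray(LP, dtype=float)
    m = L.shape[0]
    if not 1 <= k <= m:
        raise ValidationError(f"k must be in 1..{m}, got {k}")
    evals, evecs = np.linalg.eigh((L + L.T) / 2.0)
    return SpectralEmbedding(_fix_signs(evecs[:, :k]), evals[:k])


def _farthest_first(points: np.ndarray, k: int,
                    first: int | None = None) -> np.ndarray:
    """Deterministic farthest-first seed indices.

    The first seed defaults to the point nearest the centroid; each next
    seed maximizes the minimum distance to the chosen seeds (ties: lowest
    index).
    """
    m = points.shape[0]
    if first is None:
        first = int(np.argmin(np.linalg.norm(points - points.mean(axis=0), axis=1)))
    chosen = [first]
    mind = np.linalg.norm(points - points[first], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen)


def lloyd(points, init_centers, max_iter: int = 300,
          tol: float = 1e-10) -> GroupingResult:
    """Lloyd's algorithm from explicit initial centers.

    Assignment ties go to the lowest center index; an emptied cluster is
    reseeded with the point farthest from its currently assigned center
    (deterministic). Stops when assignments are unchanged or the maximum
    center shift falls below ``tol``.
    """
    X = _points(points)
    C = np.atleast_2d(np.asarray(init_centers, dtype=float))
    if C.ndim == 1 or C.shape[1] != X.shape[1]:
        C = C.reshape(-1, X.shape[1])
    k = C.shape[0]
    if k < 1 or k > X.shape[0]:
        raise ValidationError(f"k must be in 1..{X.shape[0]}, got {k}")
    C_init = C.copy()
    labels = None
    converged = False
    it = 0
    prev_inertia = np.inf
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)  # argmin ties -> lowest index
        # repair empty clusters deterministically
        repaired = False
        for j in range(k):
            if not np.any(new_labels == j):
                repaired = True
                dist_to_own = d2[np.arange(X.shape[0]), new_labels]
                cand = int(np.argmax(dist_to_own))
                new_labels[cand] = j
                d2[cand] = ((X[cand] - C) ** 2).sum(axis=1)
        newC = np.vstack([
            X[new_labels == j].mean(axis=0) for j in range(k)
        ])
        inertia = float(((X - newC[new_labels]) ** 2).sum())
        # Lloyd is monotone except across an empty-cluster repair
        assert repaired or inertia <= prev_inertia + 1e-9, \
            "Lloyd inertia increased"
        prev_inertia = inertia
        shift = float(np.max(np.linalg.norm(newC - C, axis=1)))
        unchanged = labels is not None and np.array_equal(new_labels, labels)
        labels, C = new_labels, newC
        if unchanged or shift < tol:
            converged = True
            break
    inertia = float(((X - C[labels]) ** 2).sum())
    return GroupingResult(labels, C, it, inertia, converged, C_init)


def initial_centers(points, embedding: SpectralEmbedding, k: int) -> np.ndarray:
    """Original-space initial centers from the spectral embedding.

    A deterministic k-means (farthest-first seeding) partitions the rows
    of U; each initial center is the mean of the original-space points in
    one embedded cluster. The embedded clusters are relabelled by their
    lowest member index so the output order is deterministic too.
    """
    X = _points(points)
    U = embedding.U
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds number of points {X.shape[0]}")
    seeds = _farthest_first(U, k)
    res = lloyd(U, U[seeds])
    centers = np.vstack([
        X[res.labels == j].mean(axis=0) for j in range(k)
    ])
    order = np.argsort([int(np.argmax(res.labels == j)) for j in range(k)])
    return centers[order]


def cluster_graph_kmeans(points, k: int, sigma="auto", max_iter: int = 300,
                         tol: float = 1e-10) -> GroupingResult:
    """Full pipeline: similarity -> Laplacian -> embedding -> seeding -> Lloyd.

    Deterministic given (points, k, sigma).
    """
    X = _points(points)
    G = similarity_matrix(X, sigma, n_clusters=k)
    LP = laplacian(G)
    E = spectral_embedding(LP, k)
    C0 = initial_centers(X, E, k)
    return lloyd(X, C0, max_iter=max_iter, tol=tol)


def baseline_init(points, k: int, strategy: str, seed=None) -> np.ndarray:
    """Classical seedings for benchmarking: random, k-means++ or
    farthest-first (the latter deterministic, seed ignored)."""
    X = _points(points)
    m = X.shape[0]
    if k > m:
        raise ValidationError(f"k={k} exceeds number of points {m}")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        idx = rng.choice(m, size=k, replace=False)
        return X[idx].copy()
    if strategy == "kmeanspp":
        idx = [int(rng.integers(m))]
        d2 = ((X - X[idx[0]]) ** 2).sum(axis=1)
        for _ in range(1, k):
            total = d2.sum()
            if total <= 0:
                # all remaining points coincide with a chosen center
                remaining = [i for i in range(m) if i not in idx]
                idx.append(remaining[0])
                continue
            nxt = int(rng.choice(m, p=d2 / total))
            idx.append(nxt)
            d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
        return X[idx].copy()
    if strategy == "farthest_first":
        return X[_farthest_first(X, k)].copy()
    raise UnknownMethodError(
        f"unknown init strategy {strategy!r}; known: {', '.join(INIT_STRATEGIES)}"
    )


class GraphKMeans(ClusterMixin, BaseEstimator):
    """K-means with spectral-graph (or classical) initialization.

    Parameters
    ----------
    n_clusters : int
        Number of groups k.
    sigma : float or "auto"
        Gaussian similarity bandwidth; "auto" = median pairwise distance.
    init : {"graph", "random", "kmeanspp", "farthest_first"}
        Seeding strategy. "graph" (default) is the spectral seeding and is
        fully deterministic; the others consume ``random_state``.
    max_iter, tol : Lloyd stopping controls.
    random_state : int or None
        Seed for the stochastic baselines; ignored for "graph".

    Attributes (after fit)
    ----------------------
    labels_, cluster_centers_, inertia_, n_iter_, converged_,
    initial_centers_
    """

    def __init__(self, n_clusters=6, sigma="auto", init="graph",
                 max_iter=300, tol=1e-10, random_state=None):
        self.n_clusters = n_clusters
        self.sigma = sigma
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _points(X)
        if self.init == "graph":
            res = cluster_graph_kmeans(X, self.n_clusters, self.sigma,
                                       self.max_iter, self.tol)
        elif self.init in INIT_STRATEGIES:
            C0 = baseline_init(X, self.n_clusters, self.init, self.random_state)
            res = lloyd(X, C0, self.max_iter, self.tol)
        else:
            raise UnknownMethodError(f"unknown init {self.init!r}")
        self.labels_ = res.labels
        self.cluster_centers_ = res.centers
        self.inertia_ = res.inertia
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        self.initial_centers_ = res.initial_centers
        self.result_ = res
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = _points(X)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)
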