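"""Seeded synthetic decision matrices and clustered score sets.

The generators emulate the shape of the case study — a few dozen
alternatives evaluated on a dozen-odd indicators at two time points, whose
composite scores fall into a handful of performance groups — with
controllable inter-criterion correlation (Gaussian copula), skew
(exponential tilt), outlier contamination (scale-inflated rows) and
cluster structure. Defaults match the case-study scale: m = 35
alternatives, n = 15 criteria, k = 6 groups.

All generators are pure functions of their spec (including the seed):
equal specs give bit-identical output. Each generator draws from its own
named random stream derived from the spec seed, so adding one generator
never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import BENEFIT, CriterionSpec, DecisionMatrix
from .errors import ValidationError

__all__ = [
    "SyntheticSpec",
    "generate_decision_matrix",
    "generate_clustered_scores",
    "generate_panel",
]

_STREAMS = {"matrix": 1, "scores": 2, "panel": 3}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``center_positions`` are the latent blob centers (for clustered
    scores) or per-criterion column means (for decision matrices);
    ``inter_criterion_correlation`` is the common pairwise correlation of
    the Gaussian copula; ``skew`` tilts the margins exponentially
    (0 = none); ``outlier_rate`` is the fraction of rows whose noise is
    scale-inflated 10x.
    """

    m: int = 35
    n: int = 15
    k_true: int = 6
    center_positions: tuple = ()
    noise_sd: float = 1.0
    outlier_rate: float = 0.0
    skew: float = 0.0
    inter_criterion_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 1:
            raise ValidationError("need m >= 2 and n >= 1")
        if not 0 <= self.outlier_rate <= 1:
            raise ValidationError("outlier_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not -1 <= self.inter_criterion_correlation <= 1:
            raise ValidationError("correlation must be in [-1, 1]")
        if self.k_true > self.m:
            raise ValidationError("k_true must not exceed m")


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(_STREAMS[stream],))
    )


def _correlation_chol(n: int, r: float) -> np.ndarray:
    C = np.full((n, n), r)
    np.fill_diagonal(C, 1.0)
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            f"equicorrelation {r} is not positive definite for n={n}"
        ) from exc


def generate_decision_matrix(spec: SyntheticSpec):
    """Synthetic decision matrix with known latent structure.

    Returns ``(DecisionMatrix, metadata)``; metadata records the column
    means used, the contaminated row indices and the spec itself.
    """
    rng = _rng(spec, "matrix")
    m, n = spec.m, spec.n
    means = (np.asarray(spec.center_positions, dtype=float)
             if spec.center_positions else np.zeros(n))
    if means.size == 1 and n > 1:
        means = np.full(n, float(means.ravel()[0]))
    if means.size != n:
        raise ValidationError(
            f"center_positions length {means.size} != n={n}"
        )
    Lc = _correlation_chol(n, spec.inter_criterion_correlation)
    Z = rng.standard_normal((m, n)) @ Lc.T
    if spec.skew != 0.0:
        # exponential tilt: monotone map preserving the copula
        Z = np.sign(spec.skew) * (np.exp(abs(spec.skew) * Z) - 1.0) / abs(spec.skew)
    n_out = int(np.floor(spec.outlier_rate * m))
    outlier_rows = rng.choice(m, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    scale = np.full((m, 1), spec.noise_sd)
    scale[outlier_rows] *= 10.0
    V = means + scale * Z
    X = DecisionMatrix(
        [f"A{i+1:02d}" for i in range(m)],
        [CriterionSpec(f"c{j+1:02d}", BENEFIT) for j in range(n)],
        V,
    )
    meta = {
        "spec": spec,
        "column_means": means,
        "outlier_rows": np.sort(outlier_rows),
    }
    return X, meta


def generate_clustered_scores(spec: SyntheticSpec):
    """1-D Gaussian blobs around k_true distinct centers.

    Returns ``(scores, labels, metadata)``: an (m,) score array, the true
    generating labels, and metadata with centers and contaminated rows.
    """
    rng = _rng(spec, "scores")
    centers = (np.asarray(spec.center_positions, dtype=float)
               if spec.center_positions
               else np.arange(spec.k_true, dtype=float) * 10.0)
    if centers.size != spec.k_true:
        raise ValidationError(
            f"center_positions length {centers.size} != k_true={spec.k_true}"
        )
    if np.unique(centers).size != centers.size:
        raise ValidationError("blob centers must be distinct")
    # round-robin assignment guarantees every blob is populated
    labels = np.arange(spec.m) % spec.k_true
    labels = rng.permutation(labels)
    noise = rng.standard_normal(spec.m)
    n_out = int(np.floor(spec.outlier_rate * spec.m))
    outlier_rows = rng.choice(spec.m, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    scale = np.full(spec.m, spec.noise_sd)
    scale[outlier_rows] *= 10.0
    scores = centers[labels] + scale * noise
    meta = {"spec": spec, "centers": centers, "outlier_rows": np.sort(outlier_rows)}
    return scores, labels, meta


def generate_panel(spec: SyntheticSpec, drift: float = 0.5):
    """Two decision matrices (t1, t2) with known per-cell drift.

    ``t2 = t1 + D`` where D is drawn once from the panel stream with sd
    ``drift`` (drift = 0 gives t2 == t1). Returns ``(X1, X2, metadata)``
    with the drift matrix recorded, so change-decomposition tests know the
    ground truth of which cells improved or regressed.
    """
    X1, meta1 = generate_decision_matrix(spec)
    rng = _rng(spec, "panel")
    D = drift * rng.standard_normal((spec.m, spec.n)) if drift else np.zeros((spec.m, spec.n))
    X2 = DecisionMatrix(X1.alternatives, X1.criteria, X1.values + D)
    meta = {**meta1, "drift": D}
    return X1, X2, meta
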