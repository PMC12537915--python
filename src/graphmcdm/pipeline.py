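"""End-to-end pipeline: normalize -> weight -> aggregate -> rank -> group.

A :class:`PipelineConfig` pins every choice (normalization, weighting,
aggregator, lambda, VIKOR v, sigma, k, seeding strategy, Lloyd controls),
validates each field against its domain before any computation, and is
serialized into every output's provenance header, so a result can be
reproduced from its own file.

Defaults are the model's named pipeline: logistic normalization with
prior z-scoring, DCRITIC weights, WASPAS with lambda = 0.5, and k-means
over the composite score with graph (spectral) seeding, sigma = auto,
k = 6.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any

from .aggregate import AGGREGATION_METHODS, aggregate
from .cluster import GraphKMeans, INIT_STRATEGIES
from .datamodel import DecisionMatrix, GroupingResult, RankVector, ScoreTable
from .errors import ConfigError
from .normalize import METHOD_ALIASES, normalize
from .weighting import WEIGHTING_METHODS, compute_weights

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    normalization: str = "logistic"
    standardize_first: bool = True
    weighting: str = "dcritic"
    aggregation: str = "waspas"
    lam: float = 0.5
    vikor_v: float = 0.5
    k: int = 6
    sigma: Any = "auto"
    init: str = "graph"
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.normalization not in METHOD_ALIASES:
            raise ConfigError(f"normalization {self.normalization!r} unknown")
        if self.weighting not in WEIGHTING_METHODS:
            raise ConfigError(f"weighting {self.weighting!r} unknown")
        if self.aggregation not in AGGREGATION_METHODS:
            raise ConfigError(f"aggregation {self.aggregation!r} unknown")
        for name in ("lam", "vikor_v"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        if not (isinstance(self.k, int) and self.k >= 1):
            raise ConfigError(f"k must be a positive integer, got {self.k!r}")
        if self.sigma != "auto":
            if not (isinstance(self.sigma, (int, float)) and self.sigma > 0):
                raise ConfigError(f"sigma must be positive or 'auto', got {self.sigma!r}")
        if self.init not in INIT_STRATEGIES:
            raise ConfigError(f"init {self.init!r} unknown")
        if not (isinstance(self.max_iter, int) and self.max_iter >= 1):
            raise ConfigError(f"max_iter must be >= 1, got {self.max_iter!r}")
        if not (isinstance(self.tol, (int, float)) and self.tol >= 0):
            raise ConfigError(f"tol must be >= 0, got {self.tol!r}")

    def provenance(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        alias = {"lambda": "lam"}
        kwargs = {}
        for key, val in mapping.items():
            key = alias.get(key, key)
            if key not in known:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[key] = val
        return cls(**kwargs)


@dataclass(frozen=True)
class PipelineResult:
    scores: ScoreTable | None
    ranks: RankVector
    grouping: GroupingResult | None
    weights: Any
    config: PipelineConfig

    @property
    def provenance(self) -> dict:
        return self.config.provenance()


def run_pipeline(X: DecisionMatrix, config: PipelineConfig | None = None,
                 cluster: bool = True) -> PipelineResult:
    """Run the full scoring (and optionally grouping) pipeline.

    Deterministic given (X, config): the default graph seeding has no
    randomness, and the stochastic baselines consume ``config.seed``.
    """
    cfg = config or PipelineConfig()
    kwargs = {"standardize_first": cfg.standardize_first} \
        if cfg.normalization == "logistic" else {}
    N = normalize(X, cfg.normalization, **kwargs)
    w = compute_weights(N, cfg.weighting)
    scores, ranks = aggregate(N, w, cfg.aggregation, lam=cfg.lam,
                              vikor_v=cfg.vikor_v, allow_zero=True)
    score_table = None
    if cfg.aggregation == "waspas":
        from .aggregate import waspas_score

        score_table = waspas_score(N, w, cfg.lam, allow_zero=True)
    grouping = None
    if cluster:
        merit = scores if cfg.aggregation != "vikor" else -scores
        km = GraphKMeans(n_clusters=cfg.k, sigma=cfg.sigma, init=cfg.init,
                         max_iter=cfg.max_iter, tol=cfg.tol,
                         random_state=cfg.seed)
        km.fit(merit.reshape(-1, 1))
        grouping = km.result_
    return PipelineResult(score_table, ranks, grouping, w, cfg)


def config_to_json(cfg: PipelineConfig) -> str:
    return json.dumps(cfg.provenance(), sort_keys=True)
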