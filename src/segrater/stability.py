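"""Bootstrap ranking stability of the metric battery.

A single correlation table says which metric tracks ratings best on the
full sample set, but not how robust that ordering is. Here the sample set
is repeatedly subsampled (m of n samples, without replacement), |ρ| is
recomputed per metric on each subsample, and metrics are re-ranked; the
spread of each metric's rank across replicates measures how much its
standing depends on the particular samples drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .observer import spearman_abs
from .types import MetricVector, SampleKey

__all__ = ["StabilityConfig", "RankDistribution", "bootstrap_ranks", "order_metrics"]


@dataclass
class StabilityConfig:
    """B replicates of m-of-n subsampling without replacement."""

    n_bootstrap: int = 1000
    subsample_size: int = 35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be ≥ 1")
        if self.subsample_size < 3:
            raise ValueError("subsample_size must be ≥ 3")


@dataclass
class RankDistribution:
    """Per-metric rank lists over replicates, with median/mean summaries.

    Rank 1 is best; within a replicate tied |ρ| values receive average
    ranks, so each replicate's ranks sum to M(M+1)/2 for M metrics.
    """

    ranks: dict[str, np.ndarray]
    summary: dict[str, dict[str, float]]

    @property
    def n_replicates(self) -> int:
        return len(next(iter(self.ranks.values())))


def bootstrap_ranks(
    metrics: list[MetricVector],
    ratings: dict[SampleKey, float],
    cfg: StabilityConfig | None = None,
) -> RankDistribution:
    """Rank metrics by |ρ| on each of B seeded subsamples.

    Within a replicate, metrics are ranked descending by |ρ| (rank 1 =
    strongest association). A metric whose |ρ| is undefined on a replicate
    (constant values on the subsample) takes the replicate's worst rank;
    multiple undefined metrics share it by average rank.
    """
    cfg = cfg or StabilityConfig()
    metric_names = sorted({name for mv in metrics for name in mv.values})
    samples = sorted(
        s for s in (mv.sample for mv in metrics) if s in ratings
    )
    by_sample = {mv.sample: mv.values for mv in metrics}
    n = len(samples)
    if cfg.subsample_size > n:
        raise ValueError(f"subsample_size {cfg.subsample_size} exceeds {n} samples")
    rng = np.random.default_rng(cfg.rng_seed)
    M = len(metric_names)
    ranks = {name: np.empty(cfg.n_bootstrap) for name in metric_names}
    for b in range(cfg.n_bootstrap):
        idx = rng.choice(n, size=cfg.subsample_size, replace=False)
        chosen = [samples[i] for i in idx]
        rhos = np.empty(M)
        for j, name in enumerate(metric_names):
            xs = [by_sample[s][name] for s in chosen if name in by_sample[s]]
            ys = [ratings[s] for s in chosen if name in by_sample[s]]
            try:
                rhos[j] = spearman_abs(xs, ys)
            except ValueError:
                rhos[j] = -np.inf  # undefined → worst rank of the replicate
        r = sps.rankdata(-rhos, method="average")
        for j, name in enumerate(metric_names):
            ranks[name][b] = r[j]
    summary = {
        name: {
            "median_rank": float(np.median(ranks[name])),
            "mean_rank": float(np.mean(ranks[name])),
        }
        for name in metric_names
    }
    return RankDistribution(ranks=ranks, summary=summary)


def order_metrics(dist: RankDistribution) -> list[str]:
    """Best-to-worst metric order: median rank, then mean rank, then name."""
    if not dist.ranks:
        raise ValueError("empty rank distribution")
    return sorted(
        dist.summary,
        key=lambda name: (
            dist.summary[name]["median_rank"],
            dist.summary[name]["mean_rank"],
            name,
        ),
    )
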