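"""Experience stratification and metric-rating correlation analysis.

Ratings are averaged per sample within a rater group first, then each
metric's per-sample values are correlated with those mean ratings using
the absolute Spearman coefficient: some metrics improve downward
(distances, error rates), so only the strength of the monotone
association is comparable across the battery.

A correlation that is undefined — fewer than three overlapping samples,
or a constant metric or rating vector — is reported as *missing*, never
as 0: a metric that cannot discriminate on a given stratum is a different
finding from one that discriminates badly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import EvalConfig, MetricVector, RatingRecord, SampleKey

__all__ = [
    "ExperienceGroup",
    "CorrelationEntry",
    "CorrelationTable",
    "assign_experience_group",
    "aggregate_ratings",
    "spearman_abs",
    "correlation_table",
    "classwise_correlation_table",
    "usefulness_accuracy_pearson",
    "ALL_GROUP",
]

ALL_GROUP = "all"


class ExperienceGroup(str, Enum):
    EXPERT = "expert"
    INTERMEDIATE = "intermediate"
    NOVICE = "novice"


def assign_experience_group(cases_performed: int, cases_assisted: int) -> ExperienceGroup:
    """Stratify a participant by minimally-invasive-esophagectomy case counts.

    Experts have performed more than 100 cases (past the procedure's
    learning curve); intermediates have performed or assisted more than 10
    (but performed at most 100); novices have at most 10 of either.
    Precedence expert → intermediate → novice resolves overlaps.
    """
    if cases_performed < 0 or cases_assisted < 0:
        raise ValueError("case counts must be nonnegative")
    if cases_performed > 100:
        return ExperienceGroup.EXPERT
    if cases_performed > 10 or cases_assisted > 10:
        return ExperienceGroup.INTERMEDIATE
    return ExperienceGroup.NOVICE


def aggregate_ratings(
    records: Iterable[RatingRecord],
    group: ExperienceGroup | str | None = None,
    which: str = "accuracy_rating",
) -> dict[SampleKey, float]:
    """Mean rating per sample over the selected participants.

    ``group`` of None or "all" pools every participant. Samples no selected
    participant rated are absent from the result.
    """
    if which not in ("accuracy_rating", "identification_rating"):
        raise ValueError(f"unknown rating field {which!r}")
    if isinstance(group, str) and group != ALL_GROUP:
        group = ExperienceGroup(group)
    sums: dict[SampleKey, float] = {}
    counts: dict[SampleKey, int] = {}
    selected = 0
    for rec in records:
        if group is not None and group != ALL_GROUP:
            if assign_experience_group(rec.cases_performed, rec.cases_assisted) != group:
                continue
        selected += 1
        sums[rec.sample] = sums.get(rec.sample, 0.0) + getattr(rec, which)
        counts[rec.sample] = counts.get(rec.sample, 0) + 1
    if selected == 0:
        raise ValueError(f"no ratings selected for group {group}")
    return {s: sums[s] / counts[s] for s in sums}


def spearman_abs(x: Sequence[float], y: Sequence[float]) -> float:
    """|ρ|: absolute Spearman rank correlation with average ranks for ties.

    Raises on fewer than 3 pairs or a constant input, where ρ is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("Spearman correlation requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(abs(rho))


@dataclass(frozen=True)
class CorrelationEntry:
    abs_rho: float | None  # None = undefined / missing
    n_samples: int


@dataclass
class CorrelationTable:
    """|ρ| per (metric, stratum) with the sample count each rests on."""

    entries: dict[tuple[str, str], CorrelationEntry]
    excluded_strata: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": metric,
                "stratum": stratum,
                "abs_rho": e.abs_rho if e.abs_rho is not None else np.nan,
                "n_samples": e.n_samples,
            }
            for (metric, stratum), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["metric", "stratum", "abs_rho", "n_samples"])


def _table_for_strata(
    metrics: Sequence[MetricVector],
    stratum_ratings: Mapping[str, Mapping[SampleKey, float]],
) -> CorrelationTable:
    metric_names = sorted({name for mv in metrics for name in mv.values})
    by_sample = {mv.sample: mv.values for mv in metrics}
    entries: dict[tuple[str, str], CorrelationEntry] = {}
    for stratum, ratings in stratum_ratings.items():
        for name in metric_names:
            common = [
                s for s in by_sample if name in by_sample[s] and s in ratings
            ]
            common.sort()
            xs = [by_sample[s][name] for s in common]
            ys = [ratings[s] for s in common]
            try:
                rho = spearman_abs(xs, ys)
            except ValueError:
                rho = None
            entries[(name, stratum)] = CorrelationEntry(abs_rho=rho, n_samples=len(common))
    return CorrelationTable(entries=entries)


def correlation_table(
    metrics: Sequence[MetricVector],
    records: Sequence[RatingRecord],
    groups: Sequence[ExperienceGroup | str] | None = None,
) -> CorrelationTable:
    """|ρ| between each metric and group-mean accuracy ratings.

    One entry per (metric, group); the pooled "all" stratum plus the three
    experience groups by default.
    """
    if groups is None:
        groups = [ALL_GROUP, *ExperienceGroup]
    stratum_ratings = {}
    for g in groups:
        label = g.value if isinstance(g, ExperienceGroup) else str(g)
        try:
            stratum_ratings[label] = aggregate_ratings(records, g)
        except ValueError:
            stratum_ratings[label] = {}
    return _table_for_strata(metrics, stratum_ratings)


def classwise_correlation_table(
    metrics: Sequence[MetricVector],
    records: Sequence[RatingRecord],
    config: EvalConfig | None = None,
) -> CorrelationTable:
    """Per-structure |ρ| tables over pooled-participant mean ratings.

    Structures represented by fewer than ``config.min_class_samples``
    samples are excluded (and listed in ``excluded_strata``): with one or
    two samples the correlation is trivially perfect and meaningless.
    """
    config = config or EvalConfig()
    ratings = aggregate_ratings(records, ALL_GROUP)
    structures = sorted({mv.sample.structure for mv in metrics})
    kept: dict[str, Mapping[SampleKey, float]] = {}
    excluded = []
    for structure in structures:
        sub = [mv for mv in metrics if mv.sample.structure == structure]
        if len(sub) < config.min_class_samples:
            excluded.append(structure)
            continue
        kept[structure] = ratings
    entries: dict[tuple[str, str], CorrelationEntry] = {}
    for structure, rat in kept.items():
        sub = [mv for mv in metrics if mv.sample.structure == structure]
        t = _table_for_strata(sub, {structure: rat})
        entries.update(t.entries)
    return CorrelationTable(entries=entries, excluded_strata=excluded)


def usefulness_accuracy_pearson(records: Sequence[RatingRecord]) -> float:
    """Pearson r between per-video mean identification and accuracy ratings.

    Measures whether overlays that are rated more accurate also help
    viewers identify the anatomy.
    """
    acc: dict[str, list[float]] = {}
    ident: dict[str, list[float]] = {}
    for rec in records:
        acc.setdefault(rec.sample.video_id, []).append(rec.accuracy_rating)
        ident.setdefault(rec.sample.video_id, []).append(rec.identification_rating)
    videos = sorted(acc)
    if len(videos) < 3:
        raise ValueError("Pearson correlation requires at least 3 videos")
    x = np.array([np.mean(ident[v]) for v in videos])
    y = np.array([np.mean(acc[v]) for v in videos])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant means")
    return float(stats.pearsonr(x, y).statistic)
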