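"""Shared domain types for rater-aligned segmentation evaluation.

The unit of analysis throughout the package is the *(video, structure)
sample*: one anatomical structure overlaid on one video clip. Metrics are
computed per sample from label-map sequences; ratings attach to the same
sample keys; correlation and ranking analyses consume both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np

__all__ = [
    "LabelMapSequence",
    "ProbabilitySequence",
    "SampleKey",
    "RatingRecord",
    "MetricVector",
    "EvalConfig",
]

BACKGROUND = "background"


@dataclass
class LabelMapSequence:
    """T ordered frames of H×W integer class labels.

    ``class_names[0]`` is the background class; every label value in
    ``frames`` indexes into ``class_names``. ``fps`` is informational only
    (no metric in the battery depends on wall-clock time).
    """

    frames: np.ndarray  # (T, H, W) integer labels
    class_names: list[str]
    fps: float = 25.0
    video_id: str = "video"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise ValueError(f"labels must be integers, got dtype {self.frames.dtype}")
        if not self.class_names:
            raise ValueError("class_names must be non-empty")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("negative label values")
        if self.frames.size and self.frames.max() >= len(self.class_names):
            raise ValueError(
                f"label {int(self.frames.max())} out of range for "
                f"{len(self.class_names)} classes"
            )

    @property
    def T(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def class_id(self, structure: str) -> int:
        try:
            return self.class_names.index(structure)
        except ValueError:
            raise KeyError(f"unknown structure {structure!r}") from None

    def structure_masks(self, structure: str) -> np.ndarray:
        """Boolean (T, H, W) stack of the structure's per-frame masks."""
        return self.frames == self.class_id(structure)

    def one_hot(self) -> "ProbabilitySequence":
        """Encode hard labels as a 0/1 score field (T, C, H, W)."""
        C = len(self.class_names)
        scores = np.zeros((self.T, C) + self.shape, dtype=np.float64)
        for c in range(C):
            scores[:, c] = self.frames == c
        return ProbabilitySequence(scores, list(self.class_names), self.video_id)


@dataclass
class ProbabilitySequence:
    """Per-frame, per-class nonnegative scores (T, C, H, W).

    Scores need not sum to one per pixel: hard one-hot labels, softmax
    probabilities and raw nonnegative logits are all acceptable inputs to
    temporal smoothing, whose final argmax is scale-invariant.
    """

    frames: np.ndarray  # (T, C, H, W) nonnegative scores
    class_names: list[str]
    video_id: str = "video"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be T×C×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if self.frames.shape[1] != len(self.class_names):
            raise ValueError("channel count does not match class_names")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("scores must be finite")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("scores must be nonnegative")

    @property
    def T(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True, order=True)
class SampleKey:
    """One anatomical structure in one video — a row of every analysis."""

    video_id: str
    structure: str

    def __post_init__(self) -> None:
        if self.structure == BACKGROUND:
            raise ValueError("background is not a rateable structure")


@dataclass(frozen=True)
class RatingRecord:
    """A single participant's Likert ratings of one sample.

    ``accuracy_rating`` answers "how accurate is the overlay for this
    structure"; ``identification_rating`` answers "did the overlay improve
    your ability to identify it". Experience is carried as raw case counts
    so that stratification rules stay explicit downstream.
    """

    participant_id: str
    cases_performed: int
    cases_assisted: int
    sample: SampleKey
    accuracy_rating: int
    identification_rating: int

    def __post_init__(self) -> None:
        if self.cases_performed < 0 or self.cases_assisted < 0:
            raise ValueError("case counts must be nonnegative")

    def validate_scale(self, likert_min: int, likert_max: int) -> None:
        for name in ("accuracy_rating", "identification_rating"):
            v = getattr(self, name)
            if not likert_min <= v <= likert_max:
                raise ValueError(
                    f"{name}={v} outside Likert scale [{likert_min}, {likert_max}]"
                )


@dataclass(frozen=True)
class MetricVector:
    """All metric values computed for one sample.

    A metric whose value is undefined for this sample (e.g. temporal
    consistency of a structure that is never predicted) is simply absent
    from ``values``; it is never coerced to 0 or NaN.
    """

    sample: SampleKey
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"metric {name!r} is not finite: {v}")


@dataclass
class EvalConfig:
    """Evaluation parameters shared across the metric battery and analyses.

    f_beta
        β of the F_β score; β > 1 weighs recall above precision.
    nsd_tolerance_px
        τ of the normalized surface Dice: boundary points within τ pixels
        of the other boundary count as agreeing.
    boundary_band_px
        Band half-width d (pixels) for the boundary IoU.
    hausdorff_percentile
        Percentile of directed surface distances (100 = true maximum).
    smoothing_window
        K of the weighted temporal average.
    likert_min, likert_max
        Bounds of the rating scale.
    min_class_samples
        Structures with fewer samples are excluded from class-wise
        correlation tables.
    """

    f_beta: float = 2.0
    nsd_tolerance_px: float = 2.0
    boundary_band_px: int = 2
    hausdorff_percentile: float = 100.0
    smoothing_window: int = 10
    likert_min: int = 1
    likert_max: int = 5
    rng_seed: int = 0
    min_class_samples: int = 3
    temporal_window: int = 10

    def __post_init__(self) -> None:
        if self.f_beta <= 0:
            raise ValueError("f_beta must be positive")
        if self.nsd_tolerance_px <= 0:
            raise ValueError("nsd_tolerance_px must be positive")
        if self.boundary_band_px < 1:
            raise ValueError("boundary_band_px must be ≥ 1")
        if not 0 < self.hausdorff_percentile <= 100:
            raise ValueError("hausdorff_percentile must lie in (0, 100]")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be ≥ 1")
        if self.likert_min >= self.likert_max:
            raise ValueError("likert_min must be < likert_max")
        if self.min_class_samples < 1:
            raise ValueError("min_class_samples must be positive")
        if self.temporal_window < 2:
            raise ValueError("temporal_window must be ≥ 2")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "EvalConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown EvalConfig fields: {sorted(unknown)}")
        return cls(**dict(mapping))  # type: ignore[arg-type]
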