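"""Temporal metrics and per-sample aggregation of the frame battery.

A *sample* is one structure in one video. Only *counted* frames — those
where the structure appears in the reference or the prediction — enter
the aggregation; long stretches where the structure is absent from both
carry no information about it.

Count-based metrics (dice, iou, f_beta, sensitivity, specificity, fpr,
fnr) are computed from confusion counts pooled over the counted frames,
i.e. the video is evaluated as one volume. Pooling preserves the exact
algebraic relations between paired metrics at sample level — Dice is a
monotone function of IoU, sensitivity + fnr = 1 — so paired metrics
produce identical rank correlations and can be merged in reports, which
per-frame averaging would break.

Boundary metrics (nsd, boundary_iou, hausdorff, assd) have no meaningful
pooled form across frames and are averaged per counted frame instead,
with fixed conventions for frames where exactly one mask is empty: the
bounded scores (nsd, boundary_iou) take 0 and the unbounded distances
(hausdorff, assd) take the frame diagonal √(H²+W²) as a total-miss
penalty. Temporal metrics are computed once per sequence; a rate or
metric with no defined value for a sample is omitted, never coerced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import frame_metrics as fm
from .types import EvalConfig, LabelMapSequence, MetricVector, SampleKey

__all__ = [
    "TemporalWindowConfig",
    "temporal_consistency",
    "pixel_count_variation",
    "iou_window_variation",
    "per_sample_metrics",
    "FRAME_METRICS",
    "TEMPORAL_METRICS",
    "METRIC_BATTERY",
    "HIGHER_IS_BETTER",
]

FRAME_METRICS = [
    "dice",
    "iou",
    "f_beta",
    "nsd",
    "boundary_iou",
    "hausdorff",
    "assd",
    "sensitivity",
    "specificity",
    "fpr",
    "fnr",
]
TEMPORAL_METRICS = ["temporal_consistency", "pixel_count_variation", "iou_window_variation"]
METRIC_BATTERY = FRAME_METRICS + TEMPORAL_METRICS

# Orientation of each metric (used only for reporting; correlations are
# taken in absolute value precisely because orientations differ).
HIGHER_IS_BETTER = {
    "dice": True,
    "iou": True,
    "f_beta": True,
    "nsd": True,
    "boundary_iou": True,
    "hausdorff": False,
    "assd": False,
    "sensitivity": True,
    "specificity": True,
    "fpr": False,
    "fnr": False,
    "temporal_consistency": True,
    "pixel_count_variation": False,
    "iou_window_variation": False,
}


@dataclass
class TemporalWindowConfig:
    window: int = 10

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be ≥ 2")


def temporal_consistency(pred: LabelMapSequence, structure: str) -> float:
    """Mean IoU between consecutive predicted masks of the structure.

    Reference-free: measures flicker of the displayed overlay itself.
    Pairs with both masks empty are skipped; pairs with exactly one empty
    contribute 0. Raises if the structure is never predicted (undefined).
    """
    if pred.T < 2:
        raise ValueError("temporal consistency requires at least 2 frames")
    masks = pred.structure_masks(structure)
    vals = []
    for t in range(1, pred.T):
        a, b = masks[t - 1], masks[t]
        union = np.count_nonzero(a | b)
        if union == 0:
            continue
        vals.append(np.count_nonzero(a & b) / union)
    if not vals:
        raise ValueError(f"structure {structure!r} never predicted: consistency undefined")
    return float(np.mean(vals))


def pixel_count_variation(pred: LabelMapSequence, structure: str) -> float:
    """Mean |Δ pixel count| between consecutive frames, normalised by the
    mean count (clamped to ≥ 1 so an always-absent structure scores 0)."""
    if pred.T < 2:
        raise ValueError("pixel count variation requires at least 2 frames")
    counts = pred.structure_masks(structure).sum(axis=(1, 2)).astype(np.float64)
    mean_delta = np.abs(np.diff(counts)).mean()
    return float(mean_delta / max(1.0, counts.mean()))


def iou_window_variation(
    pred: LabelMapSequence,
    ref: LabelMapSequence,
    structure: str,
    cfg: TemporalWindowConfig | None = None,
) -> float:
    """Mean sliding-window population SD of per-frame IoU vs the reference.

    Frames where both masks are empty have no defined IoU and are dropped
    before windowing; windows slide over the remaining IoU series.
    """
    cfg = cfg or TemporalWindowConfig()
    if pred.T != ref.T:
        raise ValueError("pred and ref must have equal length")
    if pred.T < cfg.window:
        raise ValueError(f"sequence shorter than window ({pred.T} < {cfg.window})")
    pm = pred.structure_masks(structure)
    rm = ref.structure_masks(structure)
    series = []
    for t in range(pred.T):
        union = np.count_nonzero(pm[t] | rm[t])
        if union == 0:
            continue
        series.append(np.count_nonzero(pm[t] & rm[t]) / union)
    if len(series) < cfg.window:
        raise ValueError("fewer defined-IoU frames than the window length")
    series = np.asarray(series)
    w = cfg.window
    sds = [float(np.std(series[i : i + w])) for i in range(len(series) - w + 1)]
    return float(np.mean(sds))


def _boundary_frame_values(
    pred_mask: np.ndarray, ref_mask: np.ndarray, config: EvalConfig, diagonal: float
) -> dict[str, float]:
    """Boundary-family values for one counted frame (ref ∪ pred nonempty)."""
    if pred_mask.any() and ref_mask.any():
        s = fm.surface_distances(pred_mask, ref_mask)
        return {
            "nsd": fm.nsd(s, config.nsd_tolerance_px),
            "boundary_iou": fm.boundary_iou(pred_mask, ref_mask, config.boundary_band_px),
            "hausdorff": fm.hausdorff(s, config.hausdorff_percentile),
            "assd": fm.assd(s),
        }
    # exactly one mask empty: bounded total-miss conventions
    return {"nsd": 0.0, "boundary_iou": 0.0, "hausdorff": diagonal, "assd": diagonal}


def per_sample_metrics(
    pred: LabelMapSequence,
    ref: LabelMapSequence,
    structure: str,
    config: EvalConfig | None = None,
) -> MetricVector:
    """Aggregate the full battery for one (video, structure) sample.

    Count-based metrics come from confusion counts pooled over counted
    frames; boundary metrics are unweighted means over counted frames;
    temporal metrics are computed once over the whole sequence. Metrics
    undefined for this sample are omitted from the result.
    """
    config = config or EvalConfig()
    if pred.frames.shape != ref.frames.shape:
        raise ValueError("pred and ref must share T, H and W")
    if pred.class_names != ref.class_names:
        raise ValueError("pred and ref must share class_names")
    pm = pred.structure_masks(structure)
    rm = ref.structure_masks(structure)
    counted = (pm | rm).any(axis=(1, 2))
    if not counted.any():
        raise ValueError(
            f"structure {structure!r} absent from both sequences in every frame"
        )
    H, W = pred.shape
    diagonal = float(np.hypot(H, W))
    pooled = fm.ConfusionCounts(0, 0, 0, 0)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for t in np.flatnonzero(counted):
        c = fm.confusion_counts(pm[t], rm[t])
        pooled = fm.ConfusionCounts(
            pooled.tp + c.tp, pooled.fp + c.fp, pooled.fn + c.fn, pooled.tn + c.tn
        )
        for name, v in _boundary_frame_values(pm[t], rm[t], config, diagonal).items():
            sums[name] = sums.get(name, 0.0) + v
            counts[name] = counts.get(name, 0) + 1
    values = {name: sums[name] / counts[name] for name in sums}
    values["dice"] = fm.dice(pooled)
    values["iou"] = fm.iou(pooled)
    values["f_beta"] = fm.f_beta(pooled, config.f_beta)
    values.update(fm.error_rates(pooled))

    if pred.T >= 2:
        try:
            values["temporal_consistency"] = temporal_consistency(pred, structure)
        except ValueError:
            pass  # never predicted → undefined, omitted
        values["pixel_count_variation"] = pixel_count_variation(pred, structure)
    if pred.T >= config.temporal_window:
        try:
            values["iou_window_variation"] = iou_window_variation(
                pred, ref, structure, TemporalWindowConfig(config.temporal_window)
            )
        except ValueError:
            pass
    return MetricVector(
        sample=SampleKey(video_id=pred.video_id, structure=structure), values=values
    )
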