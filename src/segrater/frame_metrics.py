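"""Per-frame binary-mask metrics: overlap, error-rate and surface-distance
families.

Conventions fixed across the package:

* boundaries use 4-connectivity — a mask pixel is boundary if any 4-neighbor
  lies outside the mask, where the frame edge counts as outside;
* distances are Euclidean, in pixel units, between boundary pixel centres;
* degenerate (empty-mask) frames are handled by the aggregation layer
  (`segrater.video_metrics`), not here: these functions require what their
  formulas require and raise otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "SurfaceDistanceSet",
    "confusion_counts",
    "dice",
    "iou",
    "f_beta",
    "error_rates",
    "extract_boundary",
    "surface_distances",
    "hausdorff",
    "assd",
    "nsd",
    "boundary_iou",
]

# 4-connected structuring element for boundary extraction
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion counts for one (pred, ref) mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SurfaceDistanceSet:
    """Directed boundary-to-boundary distances, one per boundary pixel."""

    d_pred_to_ref: np.ndarray
    d_ref_to_pred: np.ndarray


def _as_bool(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"{name} must be a 2-D mask")
    return mask.astype(bool)


def confusion_counts(pred_mask: np.ndarray, ref_mask: np.ndarray) -> ConfusionCounts:
    pred = _as_bool(pred_mask, "pred_mask")
    ref = _as_bool(ref_mask, "ref_mask")
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("dice undefined: both masks empty")
    return 2 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("iou undefined: both masks empty")
    return c.tp / denom


def f_beta(c: ConfusionCounts, beta: float) -> float:
    """F_β = (1+β²)·tp / ((1+β²)·tp + β²·fn + fp); β=1 recovers Dice."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    b2 = beta * beta
    denom = (1 + b2) * c.tp + b2 * c.fn + c.fp
    if denom == 0:
        raise ValueError("f_beta undefined: both masks empty")
    return (1 + b2) * c.tp / denom


def error_rates(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity/specificity and their complements.

    A rate whose denominator is zero (structure absent from ref, or ref
    covering the whole frame) is omitted from the result; callers skip the
    frame for that metric.
    """
    out: dict[str, float] = {}
    if c.tp + c.fn > 0:
        out["sensitivity"] = c.tp / (c.tp + c.fn)
        out["fnr"] = 1.0 - out["sensitivity"]
    if c.tn + c.fp > 0:
        out["specificity"] = c.tn / (c.tn + c.fp)
        out["fpr"] = 1.0 - out["specificity"]
    return out


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """(N, 2) array of (row, col) boundary-pixel coordinates.

    Boundary = mask pixels with a 4-neighbor outside the mask; the frame
    edge counts as outside (erosion with zero border).
    """
    mask = _as_bool(mask, "mask")
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~interior)


def surface_distances(pred_mask: np.ndarray, ref_mask: np.ndarray) -> SurfaceDistanceSet:
    """Directed minimum Euclidean distances between the two boundaries."""
    bp = extract_boundary(pred_mask)
    br = extract_boundary(ref_mask)
    if len(bp) == 0 or len(br) == 0:
        raise ValueError("surface distances require both masks nonempty")
    d_pr = cKDTree(br).query(bp)[0]
    d_rp = cKDTree(bp).query(br)[0]
    return SurfaceDistanceSet(d_pred_to_ref=d_pr, d_ref_to_pred=d_rp)


def hausdorff(s: SurfaceDistanceSet, percentile: float = 100.0) -> float:
    """Symmetric (percentile) Hausdorff distance; 100 → true maximum."""
    if len(s.d_pred_to_ref) == 0 or len(s.d_ref_to_pred) == 0:
        raise ValueError("empty distance set")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    return float(
        max(
            np.percentile(s.d_pred_to_ref, percentile),
            np.percentile(s.d_ref_to_pred, percentile),
        )
    )


def assd(s: SurfaceDistanceSet) -> float:
    """Average symmetric surface distance: mean over the pooled directed sets."""
    n = len(s.d_pred_to_ref) + len(s.d_ref_to_pred)
    if n == 0:
        raise ValueError("empty distance set")
    return float((s.d_pred_to_ref.sum() + s.d_ref_to_pred.sum()) / n)


def nsd(s: SurfaceDistanceSet, tolerance: float) -> float:
    """Normalized surface Dice: pooled fraction of boundary points within
    ``tolerance`` pixels of the other boundary."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    n = len(s.d_pred_to_ref) + len(s.d_ref_to_pred)
    if n == 0:
        raise ValueError("empty distance set")
    hits = np.count_nonzero(s.d_pred_to_ref <= tolerance) + np.count_nonzero(
        s.d_ref_to_pred <= tolerance
    )
    return hits / n


def _boundary_band(mask: np.ndarray, width: int) -> np.ndarray:
    """Mask pixels within Euclidean distance ``width`` of the mask boundary."""
    boundary = np.zeros(mask.shape, dtype=bool)
    coords = extract_boundary(mask)
    boundary[coords[:, 0], coords[:, 1]] = True
    # distance of every pixel to the nearest boundary pixel
    dist = ndimage.distance_transform_edt(~boundary)
    return mask & (dist <= width)


def boundary_iou(pred_mask: np.ndarray, ref_mask: np.ndarray, band_px: int) -> float:
    """IoU restricted to a band of width ``band_px`` inside each boundary."""
    if band_px < 1:
        raise ValueError("band_px must be ≥ 1")
    pred = _as_bool(pred_mask, "pred_mask")
    ref = _as_bool(ref_mask, "ref_mask")
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if not pred.any() or not ref.any():
        raise ValueError("boundary IoU requires both masks nonempty")
    bp = _boundary_band(pred, band_px)
    br = _boundary_band(ref, band_px)
    union = np.count_nonzero(bp | br)
    if union == 0:
        raise ValueError("degenerate boundary bands")
    return np.count_nonzero(bp & br) / union
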