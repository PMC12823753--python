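"""Weighted temporal averaging of per-class prediction scores.

Flickering overlays distract the viewer, so each displayed frame is a
causal weighted average of the current and previous score frames,

    F̂_t = Σ_{k=0}^{K−1} w_k · F_{t−k},      w_k = 1 − k/K,

followed by a per-pixel argmax over classes. With the default window
K = 10 the weights are 1.0, 0.9, …, 0.1: the newest frame dominates and
influence fades linearly with age. For the first K−1 frames the window is
truncated to the frames that exist, and the sum is divided by the weights
actually used so early scores stay on the same scale (the argmax itself is
scale-invariant for full windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import LabelMapSequence, ProbabilitySequence

__all__ = ["SmoothingConfig", "smooth_sequence"]


@dataclass
class SmoothingConfig:
    """Causal linear-decay smoothing window.

    ``weights[k]`` multiplies the frame k steps in the past; w_0 = 1 is
    always the largest and all weights are positive.
    """

    window: int = 10
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be ≥ 1")
        k = np.arange(self.window, dtype=np.float64)
        self.weights = 1.0 - k / self.window


def smooth_sequence(
    pred: ProbabilitySequence | LabelMapSequence, cfg: SmoothingConfig | None = None
) -> LabelMapSequence:
    """Temporally smooth a prediction sequence and emit hard labels.

    Accepts any nonnegative per-class score field; a hard label sequence is
    one-hot encoded first. Ties in the final argmax resolve to the lowest
    class index. The output has the input's length: frame t depends only
    on frames max(0, t−K+1)..t.
    """
    if isinstance(pred, LabelMapSequence):
        pred = pred.one_hot()
    cfg = cfg or SmoothingConfig()
    T = pred.T
    w = cfg.weights
    K = cfg.window
    labels = np.empty((T,) + pred.frames.shape[2:], dtype=np.int64)
    for t in range(T):
        k_max = min(K - 1, t)
        used = w[: k_max + 1]
        acc = np.tensordot(used, pred.frames[t - k_max : t + 1][::-1], axes=(0, 0))
        acc /= used.sum()
        labels[t] = np.argmax(acc, axis=0)
    return LabelMapSequence(
        frames=labels,
        class_names=list(pred.class_names),
        video_id=pred.video_id,
    )
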