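"""Synthetic study material: reference scenes, degraded predictions and
simulated raters.

The generator emulates the ingredients of a surgeon-survey evaluation of
video segmentation overlays without any real footage:

* *reference sequences* — each anatomical structure is an ellipse-like
  blob following a seeded random walk, so masks are connected, move
  smoothly and can overlap (later-listed structures overwrite earlier
  ones, exactly as in the prediction);
* *degraded predictions* — controlled instances of the error modes viewers
  actually report: boundary over-/under-segmentation (dilation/erosion),
  systematic offset (translation), boundary jitter, flicker (per-frame
  dropout), hallucinated components and systematic mislabeling;
* *simulated raters* — Likert ratings generated from each sample's latent
  quality through a group-specific linear response with leniency offset,
  sensitivity slope and Gaussian noise, then rounded and clamped to the
  scale. Making novices more lenient and less sensitive than experts
  reproduces the qualitative rating pattern of real observer studies.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, erosion
from skimage.morphology import disk as disk_footprint

from .observer import ExperienceGroup, assign_experience_group
from .types import BACKGROUND, EvalConfig, LabelMapSequence, RatingRecord, SampleKey

__all__ = [
    "StructureSpec",
    "SceneConfig",
    "DegradationConfig",
    "RaterGroupConfig",
    "generate_reference_sequence",
    "degrade_sequence",
    "simulate_ratings",
]


@dataclass(frozen=True)
class StructureSpec:
    name: str
    mean_radius_px: float
    motion_step_px: float = 1.5

    def __post_init__(self) -> None:
        if self.mean_radius_px <= 0:
            raise ValueError("mean_radius_px must be positive")
        if self.motion_step_px < 0:
            raise ValueError("motion_step_px must be nonnegative")


@dataclass
class SceneConfig:
    """Geometry of the synthetic study scenes."""

    n_videos: int = 12
    frames_per_video: int = 25
    height: int = 64
    width: int = 64
    structures: Sequence[StructureSpec] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("structures must be non-empty")
        for s in self.structures:
            # 1.1 covers the ±10% radius variation drawn per video
            if 2 * 1.1 * s.mean_radius_px >= min(self.height, self.width):
                raise ValueError(f"structure {s.name!r} cannot fit in the frame")

    @property
    def class_names(self) -> list[str]:
        return [BACKGROUND] + [s.name for s in self.structures]


@dataclass
class DegradationConfig:
    """Per-structure error injection; the all-zero config is the identity.

    dilate_erode_px
        Signed boundary offset: positive dilates (overreach), negative
        erodes (under-segmentation).
    translate_px
        Constant (dy, dx) offset of every frame's mask.
    flicker_dropout_prob
        Per-frame probability the structure's prediction is emptied.
    hallucination_prob
        Per-frame probability a spurious component of this class appears
        away from the structure's true location.
    relabel_as
        Predict this class under another class's label (systematic
        confusion, e.g. an airway labeled as pericardium).
    boundary_noise_px
        Amplitude of random per-frame boundary jitter (radius of a random
        extra dilation/erosion), producing frame-to-frame boundary wobble.
    """

    dilate_erode_px: int = 0
    translate_px: tuple[int, int] = (0, 0)
    flicker_dropout_prob: float = 0.0
    hallucination_prob: float = 0.0
    relabel_as: str | None = None
    boundary_noise_px: int = 0

    def __post_init__(self) -> None:
        for p in (self.flicker_dropout_prob, self.hallucination_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.boundary_noise_px < 0:
            raise ValueError("boundary_noise_px must be nonnegative")


@dataclass
class RaterGroupConfig:
    """Response model of one experience group.

    The latent response for sample quality q ∈ [0, 1] is
    ``likert_min + (likert_max − likert_min)·(leniency + sensitivity·q) + ε``
    with ε ~ N(0, noise_sd), rounded and clamped to the scale. Leniency
    shifts ratings upward regardless of quality; sensitivity scales how
    strongly ratings track quality.
    """

    group: ExperienceGroup
    n_raters: int
    leniency: float = 0.0
    sensitivity: float = 1.0
    noise_sd: float = 0.1
    cases_performed_range: tuple[int, int] = (0, 10)
    cases_assisted_range: tuple[int, int] = (0, 10)

    def __post_init__(self) -> None:
        if isinstance(self.group, str):
            self.group = ExperienceGroup(self.group)
        if self.n_raters < 1:
            raise ValueError("n_raters must be ≥ 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_reference_sequence(
    scene: SceneConfig,
    video_index: int,
    include: Sequence[str] | None = None,
) -> LabelMapSequence:
    """Generate one video's reference label maps.

    Each included structure gets per-video ellipse radii (±10% around its
    mean radius, keeping mean blob area near π·mean_radius²) and a
    random-walk trajectory whose per-frame displacement
    never exceeds ``motion_step_px``; trajectories reflect off the frame
    borders. Structures listed later overwrite earlier ones where they
    overlap. Deterministic in (scene.rng_seed, video_index).
    """
    rng = np.random.default_rng([abs(scene.rng_seed), video_index])
    H, W = scene.height, scene.width
    T = scene.frames_per_video
    class_names = scene.class_names
    frames = np.zeros((T, H, W), dtype=np.int64)
    for cid, spec in enumerate(scene.structures, start=1):
        # one rng draw block per structure regardless of inclusion keeps
        # the remaining structures' geometry independent of the subset
        r_y = spec.mean_radius_px * rng.uniform(0.9, 1.1)
        r_x = spec.mean_radius_px * rng.uniform(0.9, 1.1)
        rotation = rng.uniform(0, np.pi)
        margin_y, margin_x = r_y + 1, r_x + 1
        cy = rng.uniform(margin_y, H - 1 - margin_y)
        cx = rng.uniform(margin_x, W - 1 - margin_x)
        steps = rng.uniform(0, spec.motion_step_px, size=T)
        angles = rng.uniform(0, 2 * np.pi, size=T)
        selected = include is None or spec.name in include
        for t in range(T):
            if t > 0:
                cy = _reflect(cy + steps[t] * np.sin(angles[t]), margin_y, H - 1 - margin_y)
                cx = _reflect(cx + steps[t] * np.cos(angles[t]), margin_x, W - 1 - margin_x)
            if not selected:
                continue
            rr, cc = draw_ellipse(cy, cx, r_y, r_x, shape=(H, W), rotation=rotation)
            frames[t, rr, cc] = cid
    return LabelMapSequence(
        frames=frames,
        class_names=class_names,
        video_id=f"video_{video_index:02d}",
    )


def _reflect(x: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def _shift(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate a mask, filling vacated pixels with background."""
    out = np.zeros_like(mask)
    H, W = mask.shape
    ys = slice(max(dy, 0), min(H + dy, H))
    xs = slice(max(dx, 0), min(W + dx, W))
    ys_src = slice(max(-dy, 0), min(H - dy, H))
    xs_src = slice(max(-dx, 0), min(W - dx, W))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def _morph(mask: np.ndarray, px: int) -> np.ndarray:
    if px == 0 or not mask.any():
        return mask
    fp = disk_footprint(abs(px))
    out = dilation(mask, fp) if px > 0 else erosion(mask, fp)
    return out.astype(bool)


def degrade_sequence(
    ref: LabelMapSequence,
    per_structure: Mapping[str, DegradationConfig],
    seed: int,
) -> LabelMapSequence:
    """Build a prediction sequence by injecting configured errors per
    structure per frame.

    Per frame and structure, the reference mask is morphologically
    dilated/eroded, translated, jittered, dropped (flicker) and augmented
    with hallucinated components; ``relabel_as`` changes the label the
    pixels are painted with. Structures are painted in class order so
    later classes overwrite earlier ones, as in the reference; vacated
    pixels stay background. Deterministic given the seed.
    """
    for name in per_structure:
        if name not in ref.class_names or name == BACKGROUND:
            raise KeyError(f"unknown structure {name!r}")
    T = ref.T
    H, W = ref.shape
    out = np.zeros_like(ref.frames)
    for cid, name in enumerate(ref.class_names):
        if cid == 0:
            continue
        cfg = per_structure.get(name, DegradationConfig())
        rng = np.random.default_rng([abs(seed), cid])
        ref_masks = ref.frames == cid
        areas = ref_masks.sum(axis=(1, 2))
        mean_area = areas[areas > 0].mean() if (areas > 0).any() else 0.0
        halluc_radius = max(2, int(round(np.sqrt(mean_area / np.pi) / 2)))
        out_cid = cid if cfg.relabel_as is None else ref.class_names.index(cfg.relabel_as)
        for t in range(T):
            mask = ref_masks[t]
            mask = _morph(mask, cfg.dilate_erode_px)
            if cfg.translate_px != (0, 0):
                mask = _shift(mask, *cfg.translate_px)
            if cfg.boundary_noise_px > 0:
                jitter = int(rng.integers(-cfg.boundary_noise_px, cfg.boundary_noise_px + 1))
                mask = _morph(mask, jitter)
            if cfg.flicker_dropout_prob > 0 and rng.random() < cfg.flicker_dropout_prob:
                mask = np.zeros_like(mask)
            if cfg.hallucination_prob > 0 and rng.random() < cfg.hallucination_prob:
                mask = mask | _hallucinated_component(
                    rng, ref_masks[t], halluc_radius, (H, W)
                )
            out[t][mask] = out_cid
    return LabelMapSequence(
        frames=out, class_names=list(ref.class_names), fps=ref.fps, video_id=ref.video_id
    )


def _hallucinated_component(
    rng: np.random.Generator, ref_mask: np.ndarray, radius: int, shape: tuple[int, int]
) -> np.ndarray:
    """A spurious disk placed away from the structure's true location."""
    H, W = shape
    for _ in range(20):
        cy = rng.integers(radius, H - radius)
        cx = rng.integers(radius, W - radius)
        rr, cc = draw_disk((cy, cx), radius, shape=shape)
        blob = np.zeros(shape, dtype=bool)
        blob[rr, cc] = True
        if not (blob & ref_mask).any():
            return blob
    return np.zeros(shape, dtype=bool)  # frame too crowded; skip insertion


def simulate_ratings(
    quality: Mapping[SampleKey, float],
    groups: Sequence[RaterGroupConfig],
    config: EvalConfig,
    seed: int,
) -> list[RatingRecord]:
    """Simulate every rater in every group scoring every sample.

    Accuracy and identification ratings come from the same group response
    model with independent noise draws. Participant case counts are drawn
    from the group's declared ranges and verified to classify back into
    the declared group.
    """
    for key, q in quality.items():
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quality for {key} outside [0, 1]: {q}")
    lmin, lmax = config.likert_min, config.likert_max
    span = lmax - lmin
    records: list[RatingRecord] = []
    samples = sorted(quality)
    for gi, gcfg in enumerate(groups):
        rng = np.random.default_rng([abs(seed), gi])
        for r in range(gcfg.n_raters):
            performed, assisted = _draw_profile(rng, gcfg)
            pid = f"{gcfg.group.value}_{r:02d}"
            for s in samples:
                latent = gcfg.leniency + gcfg.sensitivity * quality[s]
                ratings = []
                for _ in range(2):  # accuracy, identification: independent noise
                    eps = rng.normal(0.0, gcfg.noise_sd) if gcfg.noise_sd > 0 else 0.0
                    raw = lmin + span * latent + eps
                    ratings.append(int(np.clip(np.round(raw), lmin, lmax)))
                records.append(
                    RatingRecord(
                        participant_id=pid,
                        cases_performed=performed,
                        cases_assisted=assisted,
                        sample=s,
                        accuracy_rating=ratings[0],
                        identification_rating=ratings[1],
                    )
                )
    return records


def _draw_profile(rng: np.random.Generator, gcfg: RaterGroupConfig) -> tuple[int, int]:
    lo_p, hi_p = gcfg.cases_performed_range
    lo_a, hi_a = gcfg.cases_assisted_range
    for _ in range(100):
        performed = int(rng.integers(lo_p, hi_p + 1))
        assisted = int(rng.integers(lo_a, hi_a + 1))
        if assign_experience_group(performed, assisted) == gcfg.group:
            return performed, assisted
    raise ValueError(
        f"case-count ranges never classify as {gcfg.group.value}: "
        f"performed {gcfg.cases_performed_range}, assisted {gcfg.cases_assisted_range}"
    )
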