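# Methods

`segrater` quantifies how well standard video-segmentation metrics track
human quality judgements of anatomical overlays, using a fully synthetic
observer study as its test bed. This note documents the models and
procedures, the parameters that matter, and the limits of what the
synthetic experiments can show.

## The evaluation unit

All analyses operate on *(video, structure) samples*: one anatomical
structure class overlaid on one short clip. A sample's inputs are two
`LabelMapSequence`s (reference and predicted multi-class label maps,
T×H×W integers, class 0 = background) and its outputs are a
`MetricVector` (one value per metric in the battery) and, from the rater
side, a set of Likert ratings.

## Metric battery

Four families, computed per sample.

**Count-based metrics** — Dice `2tp/(2tp+fp+fn)`, IoU `tp/(tp+fp+fn)`,
F_β `(1+β²)tp/((1+β²)tp+β²fn+fp)` (default β = 2, emphasising recall),
sensitivity, specificity, FPR, FNR — are computed from confusion counts
**pooled over the counted frames** of the sample (the frames in which
the structure appears in reference or prediction). Pooling, rather than
averaging per-frame scores, is what preserves the exact algebraic
pairings at sample level: Dice = 2·IoU/(1+IoU), sensitivity + FNR = 1,
specificity + FPR = 1. Because Spearman correlation is invariant under
strictly monotone maps, each pair then yields *identical* rank
correlations with ratings and can be merged in reports; per-frame
averaging would break this exactness. Frame averages of a
ratio are not the ratio of the pooled numerator and denominator.

**Boundary metrics** — average symmetric surface distance (ASSD),
(percentile) Hausdorff distance, normalized surface Dice (NSD, tolerance
τ = 2 px) and boundary IoU (band width d = 2 px) — have no meaningful
pooled form across frames and are unweighted means over counted frames.
Boundaries use 4-connectivity (a mask pixel with a 4-neighbour outside
the mask; the frame edge counts as outside), distances are Euclidean
between pixel centres. Degenerate frames follow fixed conventions:
both masks empty → the frame is skipped; exactly one empty → the bounded
scores (NSD, boundary IoU, and the count-based overlap contributions)
reflect a total miss, and the unbounded distances are assigned the frame
diagonal √(H²+W²) as a bounded penalty, keeping per-sample averages
finite while still penalising complete misses.

**Temporal metrics** — computed once per sample:

* *temporal consistency*: mean IoU between consecutive *predicted*
  masks. Reference-free by design: it measures flicker of the displayed
  overlay itself, which is what viewers experience.
* *pixel count variation*: mean |Δ count| between consecutive frames,
  normalised by the mean count (clamped to ≥ 1); high-frequency size
  fluctuation.
* *IoU window variation*: the per-frame prediction-vs-reference IoU
  series (frames with defined IoU), summarised as the mean population SD
  over sliding windows of length 10; low-frequency quality drift.

A metric with no defined value for a sample (e.g. temporal consistency
of a structure never predicted, or a rate with zero denominator) is
*omitted* from the `MetricVector`, never coerced to 0 or NaN; downstream
analyses work on per-metric sample intersections.

## Temporal smoothing

Predictions can be smoothed before evaluation with a causal weighted
average over a window of K frames, `F̂_t = Σ_{k<K} w_k F_{t−k}` with
`w_k = 1 − k/K` (so K = 10 gives weights 1.0, 0.9, …, 0.1), followed by a
per-pixel argmax (ties to the lowest class index). Design choices: the
window is truncated at the sequence start (padding with zeros would bias
early frames toward background) and the accumulator is divided by the
sum of the weights actually used, which only matters for those truncated
start-up frames since argmax is scale-invariant for full windows. The
input may be any nonnegative per-class score field — probabilities,
logits or one-hot labels — because the argmax does not depend on scale.

## Observer model and correlation analysis

Participants are stratified by experience from raw case counts:
expert (> 100 cases performed), intermediate (> 10 performed or
assisted, ≤ 100 performed), novice (≤ 10 of both), with precedence
expert → intermediate → novice resolving the overlap in the definitions.

Ratings are averaged per sample within a stratum first; each metric is
then correlated with those mean ratings using the **absolute Spearman
coefficient** (Pearson correlation of average ranks, ties receiving mean
ranks). The absolute value is taken because half the battery improves
downward (distances, error rates): only association strength is
comparable across metrics. A correlation is reported as *missing* —
never 0 — when fewer than 3 samples overlap or either vector is
constant; a metric that cannot discriminate on a stratum (compressed
score range) is a different finding from one that discriminates badly.

Class-wise tables repeat the analysis per structure, excluding
structures with fewer than `min_class_samples` (default 3) samples,
whose correlations would be trivially perfect. The
usefulness–accuracy analysis computes the Pearson correlation between
per-video mean identification ratings and per-video mean accuracy
ratings.

## Ranking stability

To ask how robust the metric ordering is, the sample set is subsampled B
times (default 1000 draws of m = 35 samples, ≈ 75%, *without*
replacement — a draw of distinct samples, not a classical with-replacement
bootstrap), |ρ| is recomputed per metric on each draw and metrics are
ranked descending (average ranks on ties; an undefined |ρ| takes the
draw's worst rank). Metrics are ordered by median rank, ties broken by
mean rank, then lexicographically for determinism. The spread of a
metric's rank distribution measures how sample-dependent its standing
is; it widens as m shrinks.

## Synthetic study

The generator produces the full study without any real footage.

*Scenes.* Each structure is an ellipse-like blob (per-video radii ±10%
around its mean radius, random orientation) following a seeded random
walk (default step ≤ 1.5 px/frame, reflecting at the borders). Later-
listed structures overwrite earlier ones where they overlap, in both
reference and prediction; the default scene lists structures
large-to-small so that small structures are painted on top and never
fully occluded. The default study uses 12 videos of 25 frames at
64×64 px with eight structure classes and a fixed presence matrix giving
46 samples, of which the esophagus has 1 and the thoracic duct 2 — so
the small-class exclusion path runs by default.

*Degradations.* Per structure and frame, the reference mask is passed
through: signed morphological offset (dilation = boundary overreach,
erosion = under-segmentation), constant translation, random per-frame
boundary jitter (a random extra dilation/erosion up to an amplitude),
flicker (per-frame dropout), hallucination (a spurious disk of the same
class, radius half the structure's effective radius, placed off the true
location) and optional systematic relabeling as another class. In the
default study each sample draws a severity s ~ U(0.08, 0.95) mapped to
(erosion/dilation up to ±3 px, translation up to 5 px, dropout up to
0.3, jitter up to 1.5 px, hallucination up to 0.2); this mapping was
calibrated once so the bulk (5th–95th percentile) of per-sample Dice
spans roughly 0.2–0.95, i.e. graded quality with neither floor nor
ceiling dominating, and then frozen.

*Raters.* The latent quality of a sample is its Dice score (using the
battery's own pooled definition), which makes recovery of the rater
model from the correlation analysis well-posed. A rater in group g
scores sample q as
`clamp(round(likert_min + span·(leniency_g + sensitivity_g·q) + ε))`,
ε ~ N(0, noise_sd_g), on a 1–5 scale by default. Group defaults — expert
(7 raters, sensitivity 1.0, leniency 0, σ 0.08), intermediate (11,
0.7, 0.25, 0.15), novice (8, 0.4, 0.5, 0.2) — encode the qualitative
pattern that novices rate more leniently and less discriminatively.
Identification ratings use the same model with independent noise.
Participant case counts are drawn from group-consistent ranges and
verified to classify back into the declared group.

All generators are pure functions of their configs and seeds; the
pipeline derives per-stage seeds from one global seed keyed by stage
name, so identical config + seed gives byte-identical CSV artifacts.

## What the synthetic study does and does not show

Passing tests demonstrate that the pipeline's machinery is correct
(metrics agree with brute-force oracles; rank analyses are exact on
enumerable cases) and that it *recovers by construction* the qualitative
observer patterns built into the generator: expert ratings correlate
with overlap quality more strongly than novice ratings, novices rate
higher on average, and paired monotone metrics share correlations
exactly. They do not show that real surgeons behave like the linear
rater model, that real segmentation errors decompose into these six
operators, or that blob scenes reproduce the difficulty structure of
tissue boundaries in endoscopic video. In particular the relative
ranking of metric families on synthetic data should not be read as a
clinical finding — the latent quality *is* Dice here, so overlap metrics
winning is expected, not discovered.

## Numerical choices and scales

Problem sizes throughout (64×64 frames, 25 frames/video, 46 samples,
100-seed replications, B = 1000 bootstrap draws) were chosen so the full
test suite and the acceptance script each complete in well under a
minute of compute per run while keeping every analysis statistically
non-degenerate. Spearman/Pearson coefficients come from scipy.stats;
surface distances use KD-trees on boundary pixel sets; boundary bands
use exact Euclidean distance transforms. Known limitations: metrics are
2-D per-frame (no volumetric or instance-matched variants), hallucinated
components inherit the structure's own class rather than confusing
specific class pairs unless `relabel_as` is set, and the rater model has
no per-rater bias terms beyond the group ones.
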