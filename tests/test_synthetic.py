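"""Scene generation, degradation operators and the simulated-rater model."""

import numpy as np
import pytest

from segrater import (
    DegradationConfig,
    EvalConfig,
    RaterGroupConfig,
    SampleKey,
    SceneConfig,
    StructureSpec,
    degrade_sequence,
    generate_reference_sequence,
    simulate_ratings,
)
from segrater.observer import ExperienceGroup, assign_experience_group
from segrater.study import _sample_dice, run_synthetic_study


def one_structure_scene(radius=6.0, motion=0.0, frames=10, size=32, seed=0):
    return SceneConfig(
        n_videos=1,
        frames_per_video=frames,
        height=size,
        width=size,
        structures=[StructureSpec("blob", mean_radius_px=radius, motion_step_px=motion)],
        rng_seed=seed,
    )


class TestReferenceGeneration:
    def test_static_structure_is_constant(self):
        seq = generate_reference_sequence(one_structure_scene(motion=0.0), 0)
        np.testing.assert_array_equal(seq.frames, np.broadcast_to(seq.frames[0], seq.frames.shape))
        assert seq.frames.any()

    def test_deterministic_given_seed(self):
        scene = one_structure_scene(motion=2.0, seed=42)
        a = generate_reference_sequence(scene, 3)
        b = generate_reference_sequence(scene, 3)
        np.testing.assert_array_equal(a.frames, b.frames)
        c = generate_reference_sequence(scene, 4)
        assert (a.frames != c.frames).any()

    def test_mean_area_tracks_radius(self):
        """Monte-Carlo area law: mean blob area ≈ π r² within 25%."""
        areas = []
        for v in range(5):
            scene = one_structure_scene(radius=10.0, motion=1.5, frames=100, size=48, seed=v)
            seq = generate_reference_sequence(scene, v)
            areas.append((seq.frames == 1).sum(axis=(1, 2)).mean())
        target = np.pi * 10.0**2
        assert abs(np.mean(areas) - target) / target < 0.25

    def test_displacement_bounded_by_motion_step(self):
        scene = one_structure_scene(motion=2.0, frames=30)
        seq = generate_reference_sequence(scene, 0)
        centroids = np.array(
            [np.argwhere(f == 1).mean(axis=0) for f in seq.frames]
        )
        steps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
        # rasterisation adds sub-pixel wobble on top of the walk itself
        assert steps.max() <= 2.0 + 1.5

    def test_structure_too_large_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            one_structure_scene(radius=20.0, size=32)


class TestDegradation:
    @pytest.fixture
    def ref(self):
        return generate_reference_sequence(one_structure_scene(motion=1.0, frames=8), 0)

    def test_zero_config_is_identity(self, ref):
        pred = degrade_sequence(ref, {"blob": DegradationConfig()}, seed=0)
        np.testing.assert_array_equal(pred.frames, ref.frames)

    def test_unconfigured_structures_pass_through(self, ref):
        pred = degrade_sequence(ref, {}, seed=0)
        np.testing.assert_array_equal(pred.frames, ref.frames)

    def test_unknown_structure_rejected(self, ref):
        with pytest.raises(KeyError):
            degrade_sequence(ref, {"no_such": DegradationConfig()}, seed=0)

    def test_full_dropout_empties_every_frame(self, ref):
        pred = degrade_sequence(ref, {"blob": DegradationConfig(flicker_dropout_prob=1.0)}, seed=1)
        assert not pred.frames.any()
        assert _sample_dice(pred, ref, "blob") == 0.0

    def test_dilation_keeps_sensitivity_one(self):
        """+2 px dilation covers the reference: sensitivity 1, precision < 1."""
        ref = generate_reference_sequence(one_structure_scene(motion=0.0, frames=2), 0)
        pred = degrade_sequence(ref, {"blob": DegradationConfig(dilate_erode_px=2)}, seed=0)
        p = pred.frames[0] == 1
        r = ref.frames[0] == 1
        tp = np.count_nonzero(p & r)
        fp = np.count_nonzero(p & ~r)
        fn = np.count_nonzero(~p & r)
        assert fn == 0 and tp > 0  # sensitivity = 1
        assert fp > 0  # precision < 1

    def test_dice_monotone_in_boundary_offset(self):
        """Growing |dilate_erode_px| never improves Dice on a static scene."""
        ref = generate_reference_sequence(one_structure_scene(radius=8.0, motion=0.0, frames=4), 0)
        for sign in (+1, -1):
            dices = []
            for px in range(0, 5):
                pred = degrade_sequence(
                    ref, {"blob": DegradationConfig(dilate_erode_px=sign * px)}, seed=0
                )
                dices.append(_sample_dice(pred, ref, "blob"))
            assert all(a >= b - 1e-12 for a, b in zip(dices, dices[1:]))

    def test_relabel_moves_pixels_to_other_class(self):
        scene = SceneConfig(
            n_videos=1, frames_per_video=3, height=48, width=48,
            structures=[
                StructureSpec("a", mean_radius_px=6, motion_step_px=0.0),
                StructureSpec("b", mean_radius_px=5, motion_step_px=0.0),
            ],
            rng_seed=5,
        )
        ref = generate_reference_sequence(scene, 0)
        pred = degrade_sequence(ref, {"a": DegradationConfig(relabel_as="b")}, seed=0)
        assert not (pred.frames == 1).any()
        # pixels that were class a are now class b unless overwritten
        assert ((ref.frames == 1) & (pred.frames == 2)).any()

    def test_hallucination_adds_disjoint_component(self):
        ref = generate_reference_sequence(one_structure_scene(radius=5.0, motion=0.0, frames=6), 0)
        pred = degrade_sequence(
            ref, {"blob": DegradationConfig(hallucination_prob=1.0)}, seed=2
        )
        extra = (pred.frames == 1) & ~(ref.frames == 1)
        assert extra.any(axis=(1, 2)).sum() >= 5  # most frames gain a spurious blob

    def test_deterministic_given_seed(self, ref):
        cfg = {"blob": DegradationConfig(flicker_dropout_prob=0.4, boundary_noise_px=1)}
        a = degrade_sequence(ref, cfg, seed=9)
        b = degrade_sequence(ref, cfg, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestRaterModel:
    def key(self, i=0):
        return SampleKey(video_id=f"v{i}", structure="s")

    def group(self, **kw):
        defaults = dict(group=ExperienceGroup.NOVICE, n_raters=1, leniency=0.0,
                        sensitivity=1.0, noise_sd=0.0,
                        cases_performed_range=(0, 10), cases_assisted_range=(0, 10))
        defaults.update(kw)
        return RaterGroupConfig(**defaults)

    def test_noiseless_extremes_hit_scale_ends(self):
        cfg = EvalConfig()
        recs = simulate_ratings({self.key(0): 1.0, self.key(1): 0.0}, [self.group()], cfg, seed=0)
        by_video = {r.sample.video_id: r.accuracy_rating for r in recs}
        assert by_video["v0"] == 5
        assert by_video["v1"] == 1

    def test_quality_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="quality"):
            simulate_ratings({self.key(): 1.2}, [self.group()], EvalConfig(), seed=0)

    def test_profiles_classify_into_declared_group(self):
        groups = [
            self.group(group=ExperienceGroup.EXPERT, n_raters=5,
                       cases_performed_range=(101, 300), cases_assisted_range=(0, 300)),
            self.group(group=ExperienceGroup.INTERMEDIATE, n_raters=5,
                       cases_performed_range=(11, 100), cases_assisted_range=(0, 100)),
            self.group(group=ExperienceGroup.NOVICE, n_raters=5),
        ]
        recs = simulate_ratings({self.key(): 0.5}, groups, EvalConfig(), seed=3)
        for r in recs:
            declared = ExperienceGroup(r.participant_id.rsplit("_", 1)[0])
            assert assign_experience_group(r.cases_performed, r.cases_assisted) == declared

    def test_impossible_profile_range_rejected(self):
        bad = self.group(group=ExperienceGroup.EXPERT)  # novice-range counts
        with pytest.raises(ValueError, match="never classify"):
            simulate_ratings({self.key(): 0.5}, [bad], EvalConfig(), seed=0)

    def test_novices_rate_higher_and_track_quality_worse(self):
        """Lenient low-sensitivity novices vs faithful experts, many seeds."""
        from segrater.observer import spearman_abs

        rng = np.random.default_rng(0)
        quality = {SampleKey(f"v{i}", "s"): float(q)
                   for i, q in enumerate(rng.uniform(0.2, 0.95, size=46))}
        expert = self.group(group=ExperienceGroup.EXPERT, n_raters=7, sensitivity=1.0,
                            leniency=0.0, noise_sd=0.08,
                            cases_performed_range=(101, 300), cases_assisted_range=(0, 300))
        novice = self.group(n_raters=8, sensitivity=0.4, leniency=0.5, noise_sd=0.2)
        mean_wins = rho_wins = 0
        trials = 30
        keys = sorted(quality)
        for seed in range(trials):
            recs = simulate_ratings(quality, [expert, novice], EvalConfig(), seed=seed)
            e = [r.accuracy_rating for r in recs if r.participant_id.startswith("expert")]
            n = [r.accuracy_rating for r in recs if r.participant_id.startswith("novice")]
            mean_wins += np.mean(n) > np.mean(e)
            by = {}
            for r in recs:
                by.setdefault(r.participant_id.rsplit("_", 1)[0], {}).setdefault(
                    r.sample, []
                ).append(r.accuracy_rating)
            rho = {
                g: spearman_abs([quality[k] for k in keys], [np.mean(v[k]) for k in keys])
                for g, v in by.items()
            }
            rho_wins += rho["expert"] > rho["novice"]
        assert mean_wins >= int(0.9 * trials)
        assert rho_wins >= int(0.9 * trials)


def test_default_study_is_deterministic_and_complete():
    a = run_synthetic_study(seed=11, full_metrics=False)
    b = run_synthetic_study(seed=11, full_metrics=False)
    assert a.quality == b.quality
    assert a.records == b.records
    assert len(a.quality) == 46
    assert len({k.video_id for k in a.quality}) == 12
    assert len(a.records) == 26 * 46  # every rater rates every sample
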