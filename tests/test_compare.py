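import numpy as np
import pytest

from gesturedtw.compare import (
    adopt_mirror_candidate,
    hand_distance,
    mirror_flip,
    mirrored_pair_distance,
    pair_distance,
)
from gesturedtw.segment import GestureClip
from gesturedtw.stats import spearman
from gesturedtw.synthetic import GestureSpec, mirror_series, render_gesture
from conftest import rendered_clip


def spec(hand="right", **kw):
    return GestureSpec(hand=hand, **kw)


class TestHandDistance:
    def test_identical_clips_same_hand_zero(self):
        clip = rendered_clip(spec())
        d, per_kp = hand_distance(clip.series, clip.series, "right", "right")
        assert d == pytest.approx(0.0, abs=1e-12)
        assert len(per_kp) == 6

    def test_per_hand_is_mean_of_six_keypoints(self):
        a = rendered_clip(spec(), seed=1, noise_sd=0.005)
        b = rendered_clip(spec(trajectory_kind="arc"), seed=2, noise_sd=0.005)
        d, per_kp = hand_distance(a.series, b.series, "right", "right")
        assert d == pytest.approx(np.mean(list(per_kp.values())))
        assert all(v >= 0 for v in per_kp.values())

    def test_unknown_hand_rejected(self):
        clip = rendered_clip(spec())
        with pytest.raises(KeyError):
            hand_distance(clip.series, clip.series, "dorsal", "right")

    def test_distance_increases_with_noise(self):
        base = rendered_clip(spec(), seed=5)
        levels = np.linspace(0.0, 0.05, 20)
        dists = []
        for i, sd in enumerate(levels):
            noisy = rendered_clip(spec(), seed=5, noise_sd=float(sd))
            d, _ = hand_distance(base.series, noisy.series, "right", "right")
            dists.append(d)
        rho = spearman(levels, np.array(dists)).rho
        assert rho >= 0.9


class TestMirrorFlip:
    def test_involution(self):
        clip = rendered_clip(spec(), noise_sd=0.004)
        back = mirror_flip(mirror_flip(clip.series))
        np.testing.assert_allclose(back.data, clip.series.data, atol=1e-12)

    def test_left_gesture_becomes_right_with_negated_x(self):
        clip = rendered_clip(spec(hand="left"))
        flipped = mirror_flip(clip.series)
        np.testing.assert_allclose(
            flipped.get("right_wrist")[:, 0],
            -clip.series.get("left_wrist")[:, 0],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            flipped.get("right_wrist")[:, 1],
            clip.series.get("left_wrist")[:, 1],
            atol=1e-12,
        )

    def test_flip_maps_per_hand_distance_to_mirror_counterpart(self):
        a = rendered_clip(spec(hand="left"), seed=3, noise_sd=0.004)
        b = rendered_clip(spec(hand="left", trajectory_kind="circle"),
                          seed=4, noise_sd=0.004)
        d_left, _ = hand_distance(a.series, b.series, "left", "left")
        d_right, _ = hand_distance(
            mirror_flip(a.series), mirror_flip(b.series), "right", "right"
        )
        assert d_right == pytest.approx(d_left, abs=1e-9)


class TestMirrorRule:
    @pytest.mark.parametrize(
        "original, flipped, expected, used",
        [
            (0.5, 0.1, 0.1, True),
            (0.1, 0.5, 0.1, False),
            (0.3, 0.3, 0.3, False),  # tie keeps the original orientation
        ],
    )
    def test_minimum_selection(self, original, flipped, expected, used):
        value, mirror_used = adopt_mirror_candidate(original, flipped)
        assert value == expected and mirror_used == used

    def test_exact_mirror_pair_adopts_flipped_at_zero(self):
        s = spec(hand="right", trajectory_kind="arc", orientation_angle=0.8)
        a = rendered_clip(s, seed=0)
        b_series = mirror_series(render_gesture(s, np.random.default_rng(0)))
        b = GestureClip(
            segment=a.segment.__class__(
                "d", "B", "t", a.segment.t_start, a.segment.t_end, "left"
            ),
            series=_preprocess_like(a, b_series),
            start_frame=a.start_frame,
            end_frame=a.end_frame,
        )
        res = mirrored_pair_distance(a, b)
        assert res.mirror_used
        assert res.pair_distance == pytest.approx(0.0, abs=1e-9)

    def test_never_increases_distance(self):
        rng = np.random.default_rng(7)
        for k in range(10):
            a = rendered_clip(spec(hand="right",
                                   direction=float(rng.uniform(0, 6))),
                              seed=k, noise_sd=0.005)
            b = rendered_clip(spec(hand="left",
                                   direction=float(rng.uniform(0, 6))),
                              seed=100 + k, noise_sd=0.005)
            with_rule = pair_distance(a, b, mirror=True)
            without = pair_distance(a, b, mirror=False)
            assert with_rule.pair_distance <= without.pair_distance + 1e-12

    def test_rejects_same_handed_and_two_handed_pairs(self):
        a = rendered_clip(spec(hand="right"))
        b = rendered_clip(spec(hand="right"), seed=1)
        with pytest.raises(ValueError):
            mirrored_pair_distance(a, b)
        c = rendered_clip(spec(hand="both"), seed=2)
        with pytest.raises(ValueError):
            mirrored_pair_distance(a, c)


def _preprocess_like(reference_clip, raw_series):
    """Preprocess a raw series and cut the same frame window as a clip."""
    from gesturedtw.preprocess import run_pipeline

    processed, _ = run_pipeline(raw_series)
    return processed.slice_frames(
        reference_clip.start_frame, reference_clip.end_frame
    )


class TestPairDistance:
    def test_self_pair_is_zero_two_handed(self):
        clip = rendered_clip(spec(hand="both"))
        res = pair_distance(clip, clip)
        assert res.pair_distance == pytest.approx(0.0, abs=1e-12)
        assert res.branch == "both-both"

    def test_two_handed_pair_averages_both_hands(self):
        a = rendered_clip(spec(hand="both"), seed=1, noise_sd=0.004)
        b = rendered_clip(spec(hand="both", trajectory_kind="arc"),
                          seed=2, noise_sd=0.004)
        res = pair_distance(a, b)
        assert res.pair_distance == pytest.approx(
            np.mean(list(res.per_hand.values()))
        )
        assert set(res.per_hand) == {"left|left", "right|right"}

    def test_same_single_hand_uses_that_hand_only(self):
        # identical left hands, unrelated right hands: distance must be 0
        a = rendered_clip(spec(hand="left"), seed=3)
        b = rendered_clip(spec(hand="left"), seed=3)
        res = pair_distance(a, b)
        assert res.branch == "one-handed-same"
        assert res.pair_distance == pytest.approx(0.0, abs=1e-12)
        assert set(res.per_hand) == {"left|left"}

    def test_opposite_hands_compare_across_hands(self):
        a = rendered_clip(spec(hand="left"), seed=4, noise_sd=0.004)
        b = rendered_clip(spec(hand="right"), seed=5, noise_sd=0.004)
        res = pair_distance(a, b, mirror=False)
        expected, _ = hand_distance(a.series, b.series, "left", "right")
        assert res.pair_distance == pytest.approx(expected)

    def test_one_vs_two_handed_takes_minimum(self):
        a = rendered_clip(spec(hand="right"), seed=6, noise_sd=0.004)
        b = rendered_clip(spec(hand="both"), seed=7, noise_sd=0.004)
        res = pair_distance(a, b)
        assert res.branch == "one-vs-two"
        assert res.pair_distance == pytest.approx(min(res.per_hand.values()))
        assert len(res.per_hand) == 2
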