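import math

import numpy as np
import pytest

from conftest import make_flat_series, random_series
from gesturedtw.landmarks import LANDMARKS
from gesturedtw.preprocess import (
    ASPECT_16_9,
    DegenerateSkeletonError,
    PreprocessConfig,
    adjust_aspect,
    interpolate_missing,
    invert_y,
    normalize_position,
    normalize_size,
    relative_fingertips,
    run_pipeline,
    smooth,
)
from gesturedtw.timeseries import SkeletonTimeSeries


def body_series(n_frames=12, fps=30.0, offset=(0.0, 0.0, 0.0), scale=1.0):
    """Deterministic full skeleton with a moving right hand and a rigid,
    vertically aligned torso (torso length exactly 0.24 * scale)."""
    data = np.zeros((n_frames, len(LANDMARKS), 3))
    idx = {n: i for i, n in enumerate(LANDMARKS)}
    pos = {
        "left_shoulder": (0.4, 0.38),
        "right_shoulder": (0.6, 0.38),
        "left_hip": (0.4, 0.62),
        "right_hip": (0.6, 0.62),
        "left_wrist": (0.35, 0.6),
        "right_wrist": (0.65, 0.45),
    }
    t = np.arange(n_frames) / fps
    for name, (x, y) in pos.items():
        data[:, idx[name], 0] = x
        data[:, idx[name], 1] = y
    data[:, idx["right_wrist"], 0] += 0.08 * np.sin(2 * np.pi * t)
    for side in ("left", "right"):
        for k, tip in enumerate(
            ("thumb_tip", "index_tip", "middle_tip", "ring_tip", "pinky_tip")
        ):
            data[:, idx[f"{side}_{tip}"], :] = data[:, idx[f"{side}_wrist"], :]
            data[:, idx[f"{side}_{tip}"], 0] += 0.01 * (k + 1)
            data[:, idx[f"{side}_{tip}"], 1] -= 0.02
    data = data * scale + np.asarray(offset)
    return SkeletonTimeSeries(data=data, fps=fps)


class TestInterpolation:
    def test_interior_gap_filled_linearly(self):
        series = make_flat_series([1, 2, np.nan, np.nan, 5])
        out = interpolate_missing(series)
        np.testing.assert_allclose(out.data[:, 0, 0], [1, 2, 3, 4, 5])

    def test_edge_gaps_copy_nearest_observation(self):
        series = make_flat_series([np.nan, 4, np.nan])
        out = interpolate_missing(series)
        np.testing.assert_allclose(out.data[:, 0, 0], [4, 4, 4])

    def test_fully_observed_series_unchanged_and_idempotent(self, rng):
        series = random_series(rng, missing_rate=0.2)
        once = interpolate_missing(series)
        assert not np.isnan(once.data).any()
        twice = interpolate_missing(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_all_missing_track_is_an_error(self):
        series = make_flat_series([1.0, 2.0, 3.0])
        data = series.data.copy()
        data[:, 2, 1] = np.nan
        with pytest.raises(ValueError, match=LANDMARKS[2]):
            interpolate_missing(series.with_data(data))


class TestSmoothing:
    def test_constant_series_unchanged(self):
        series = make_flat_series([0.7] * 30)
        out = smooth(series, sigma=2.0)
        np.testing.assert_allclose(out.data, series.data, atol=1e-12)

    def test_sigma_zero_is_identity(self, rng):
        series = random_series(rng)
        out = smooth(series, sigma=0.0)
        np.testing.assert_array_equal(out.data, series.data)

    def test_impulse_response_equals_normalized_gaussian_kernel(self):
        sigma = 2.0
        n = 101
        series = make_flat_series([0.0] * n)
        data = series.data.copy()
        data[50, :, :] = 1.0
        out = smooth(series.with_data(data), sigma=sigma)
        radius = int(4.0 * sigma + 0.5)
        k = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (k / sigma) ** 2)
        kernel /= kernel.sum()
        np.testing.assert_allclose(
            out.data[50 - radius : 50 + radius + 1, 0, 0], kernel, atol=1e-12
        )

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth(random_series(rng), sigma=-1.0)


class TestPositionNormalization:
    def test_mid_torso_at_origin_every_frame(self):
        out, _ = normalize_position(body_series())
        torso = [out.get(n) for n in
                 ("left_shoulder", "right_shoulder", "left_hip", "right_hip")]
        mid = sum(torso) / 4.0
        np.testing.assert_allclose(mid, 0.0, atol=1e-12)

    def test_translation_invariance(self):
        base, _ = normalize_position(body_series())
        shifted, _ = normalize_position(body_series(offset=(0.3, -0.2, 0.5)))
        np.testing.assert_allclose(shifted.data, base.data, atol=1e-9)

    def test_keypoint_left_of_torso_has_negative_x(self):
        out, _ = normalize_position(body_series())
        assert (out.get("left_wrist")[:, 0] < 0).all()


class TestSizeNormalization:
    def test_torso_length_one_after_scaling(self):
        centered, info = normalize_position(body_series())
        out = normalize_size(centered, info)
        ls, rs = out.get("left_shoulder"), out.get("right_shoulder")
        lh, rh = out.get("left_hip"), out.get("right_hip")
        d = np.linalg.norm((ls + rs) / 2 - (lh + rh) / 2, axis=1)
        np.testing.assert_allclose(d, 1.0, atol=1e-6)

    def test_scale_invariance(self):
        a, ia = normalize_position(body_series())
        b, ib = normalize_position(body_series(scale=2.0))
        np.testing.assert_allclose(
            normalize_size(b, ib).data, normalize_size(a, ia).data, atol=1e-9
        )

    def test_degenerate_torso_rejected(self):
        series = make_flat_series([0.5] * 5)  # all landmarks coincide
        with pytest.raises(DegenerateSkeletonError):
            normalize_position(series)


class TestAspectAndInversion:
    def test_x_displacement_scaled_to_match_vertical(self):
        series = make_flat_series([0.0, 0.1])
        out = adjust_aspect(series, ASPECT_16_9)
        assert round(out.data[1, 0, 0] - out.data[0, 0, 0], 3) == 0.178

    def test_y_and_z_untouched_and_unit_ratio_is_identity(self, rng):
        series = random_series(rng)
        out = adjust_aspect(series, ASPECT_16_9)
        np.testing.assert_array_equal(out.data[:, :, 1:], series.data[:, :, 1:])
        ident = adjust_aspect(series, 1.0)
        np.testing.assert_array_equal(ident.data, series.data)

    def test_y_inversion_is_involution(self, rng):
        series = random_series(rng)
        once = invert_y(series)
        np.testing.assert_allclose(once.data[:, :, 1], -series.data[:, :, 1])
        np.testing.assert_array_equal(invert_y(once).data, series.data)

    def test_point_above_torso_positive_y_after_inversion(self):
        centered, _ = normalize_position(body_series())
        out = invert_y(centered)
        # shoulders sit above the mid-torso
        assert (out.get("left_shoulder")[:, 1] > 0).all()


class TestRelativeFingertips:
    def test_worked_displacement_example(self):
        series = make_flat_series([0.0] * 3)
        data = series.data.copy()
        iw = series.landmark_index("right_wrist")
        ii = series.landmark_index("right_index_tip")
        data[:, iw, :2] = [1.0, 1.0]
        data[:, ii, :2] = [1.3, 2.2]
        out = relative_fingertips(series.with_data(data))
        np.testing.assert_allclose(out.data[:, ii, :2], [[0.3, 1.2]] * 3)
        # translating the whole hand leaves the relative position identical
        data2 = data.copy()
        data2[:, iw, :2] = [2.0, 2.0]
        data2[:, ii, :2] = [2.3, 3.2]
        out2 = relative_fingertips(series.with_data(data2))
        np.testing.assert_allclose(out2.data[:, ii, :2], [[0.3, 1.2]] * 3)

    def test_coincident_tip_maps_to_origin_and_wrist_unchanged(self):
        series = body_series()
        data = series.data.copy()
        it = series.landmark_index("left_thumb_tip")
        iw = series.landmark_index("left_wrist")
        data[:, it, :] = data[:, iw, :]
        out = relative_fingertips(series.with_data(data))
        np.testing.assert_allclose(out.data[:, it, :], 0.0, atol=1e-12)
        np.testing.assert_array_equal(out.data[:, iw, :], data[:, iw, :])


class TestPipeline:
    def test_equals_manual_composition(self, rng):
        series = random_series(rng, missing_rate=0.1)
        cfg = PreprocessConfig()
        manual = interpolate_missing(series)
        manual = smooth(manual, cfg.sigma)
        manual, info = normalize_position(manual)
        manual = normalize_size(manual, info)
        manual = adjust_aspect(manual, cfg.aspect_ratio)
        manual = invert_y(manual)
        manual = relative_fingertips(manual)
        out, _ = run_pipeline(series, cfg)
        np.testing.assert_array_equal(out.data, manual.data)

    def test_gaps_eliminated(self, rng):
        out, _ = run_pipeline(random_series(rng, missing_rate=0.15))
        assert not np.isnan(out.data).any()

    def test_translation_and_scale_invariance(self):
        base, _ = run_pipeline(body_series())
        moved, _ = run_pipeline(body_series(offset=(0.25, -0.1, 0.4)))
        np.testing.assert_allclose(moved.data, base.data, atol=1e-9)
        scaled, _ = run_pipeline(body_series(scale=math.pi / 2))
        np.testing.assert_allclose(scaled.data, base.data, atol=1e-6)
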