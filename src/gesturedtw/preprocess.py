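"""Keypoint time-series preprocessing chain.

The chain turns raw tracker output (normalized image coordinates, y down,
speaker anywhere in frame) into body-centered, size-free kinematics:

1. linear interpolation of occlusion gaps,
2. Gaussian smoothing against tracker jitter,
3. per-frame centering on the mid-torso,
4. division by torso length (mid-shoulder to mid-hip distance),
5. x-axis stretch by the video aspect ratio so x and y share units,
6. y-axis inversion so up is positive,
7. fingertips re-expressed relative to the same hand's wrist.

After step 7, wrist trajectories carry hand position and movement while
fingertip channels carry handshape and orientation, independent of where
the hand sits in gesture space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .landmarks import FINGERTIPS, SIDES, TORSO
from .timeseries import SkeletonTimeSeries

#: width/height of a 16:9 video frame, kept exact rather than rounded to 1.78
ASPECT_16_9 = 16.0 / 9.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the preprocessing chain.

    sigma
        Gaussian smoothing standard deviation, in frames.
    aspect_ratio
        Multiplier applied to x so horizontal and vertical displacements
        are commensurate (width/height of the video).
    use_z
        Whether the heuristic depth coordinate participates in distance
        computation downstream.
    """

    sigma: float = 2.0
    aspect_ratio: float = ASPECT_16_9
    use_z: bool = False

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.aspect_ratio > 0:
            raise ValueError("aspect_ratio must be positive")


@dataclass(frozen=True)
class NormalizationInfo:
    """Centering origin and size scale extracted during normalization."""

    mid_torso: np.ndarray  # (n_frames, 3)
    torso_length: float

    def __post_init__(self):
        if not self.torso_length > 0:
            raise ValueError("torso_length must be positive")


class DegenerateSkeletonError(ValueError):
    """Torso geometry too degenerate to define a size scale."""


def interpolate_missing(series: SkeletonTimeSeries) -> SkeletonTimeSeries:
    """Fill NaN gaps per landmark-coordinate track.

    Interior gaps are filled linearly between the flanking observations;
    leading/trailing gaps copy the nearest observed value. A track with no
    observation at all is an error — the caller must drop the landmark.
    """
    data = series.data.copy()
    n = series.n_frames
    t = np.arange(n)
    for j, name in enumerate(series.landmark_names):
        for k in range(3):
            track = data[:, j, k]
            obs = ~np.isnan(track)
            if obs.all():
                continue
            if not obs.any():
                raise ValueError(
                    f"landmark {name!r} axis {k} has no observed values"
                )
            # np.interp clamps outside the observed range -> edge copy
            data[:, j, k] = np.interp(t, t[obs], track[obs])
    return series.with_data(data)


def smooth(series: SkeletonTimeSeries, sigma: float = 2.0) -> SkeletonTimeSeries:
    """Gaussian-smooth every track (reflect padding, 4-sigma truncation)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if np.isnan(series.data).any():
        raise ValueError("smooth requires a gap-free series; interpolate first")
    if sigma == 0:
        return series.copy()
    data = gaussian_filter1d(
        series.data, sigma=sigma, axis=0, mode="reflect", truncate=4.0
    )
    return series.with_data(data)


def _torso_points(series: SkeletonTimeSeries):
    ls, rs, lh, rh = (series.get(n) for n in TORSO)
    mid_shoulder = (ls + rs) / 2.0
    mid_hip = (lh + rh) / 2.0
    mid_torso = (ls + rs + lh + rh) / 4.0
    return mid_shoulder, mid_hip, mid_torso


def normalize_position(
    series: SkeletonTimeSeries,
) -> tuple[SkeletonTimeSeries, NormalizationInfo]:
    """Center every frame on the mid-torso.

    The mid-torso (mean of both shoulders and both hips) maps to the
    origin in every frame; all other keypoints become relative to it. The
    returned :class:`NormalizationInfo` also carries the torso length: the
    median across frames of the 3D mid-shoulder to mid-hip distance, a
    robust per-recording size scale.
    """
    mid_shoulder, mid_hip, mid_torso = _torso_points(series)
    if np.isnan(mid_torso).any():
        raise ValueError("torso landmarks contain gaps; interpolate first")
    torso_length = float(
        np.median(np.linalg.norm(mid_shoulder - mid_hip, axis=1))
    )
    if torso_length <= 1e-6:
        raise DegenerateSkeletonError(
            f"torso length {torso_length:g} too small to define a size scale"
        )
    data = series.data - mid_torso[:, None, :]
    return series.with_data(data), NormalizationInfo(
        mid_torso=mid_torso, torso_length=torso_length
    )


def normalize_size(
    series: SkeletonTimeSeries, info: NormalizationInfo
) -> SkeletonTimeSeries:
    """Divide all coordinates by the torso length.

    After this step distances are in torso units: a value of 1 equals one
    mid-shoulder-to-mid-hip length, making speakers of different apparent
    sizes (height, camera proximity) directly comparable.
    """
    if info.torso_length <= 1e-6:
        raise DegenerateSkeletonError(
            f"torso length {info.torso_length:g} too small"
        )
    return series.with_data(series.data / info.torso_length)


def adjust_aspect(
    series: SkeletonTimeSeries, aspect_ratio: float = ASPECT_16_9
) -> SkeletonTimeSeries:
    """Multiply x by the video aspect ratio; y and z are untouched."""
    if not aspect_ratio > 0:
        raise ValueError("aspect_ratio must be positive")
    data = series.data.copy()
    data[:, :, 0] *= aspect_ratio
    return series.with_data(data)


def invert_y(series: SkeletonTimeSeries) -> SkeletonTimeSeries:
    """Flip the y-axis so larger values mean higher in space (involution)."""
    data = series.data.copy()
    data[:, :, 1] *= -1.0
    return series.with_data(data)


def relative_fingertips(series: SkeletonTimeSeries) -> SkeletonTimeSeries:
    """Re-express each fingertip as its displacement from the same wrist.

    Wrist channels keep hand position; fingertip channels become pure
    handshape/orientation information, invariant to where the hand is.
    """
    data = series.data.copy()
    for side in SIDES:
        wrist = series.get(f"{side}_wrist")
        for tip in FINGERTIPS:
            idx = series.landmark_index(f"{side}_{tip}")
            data[:, idx, :] = series.data[:, idx, :] - wrist
    return series.with_data(data)


def run_pipeline(
    series: SkeletonTimeSeries, config: PreprocessConfig | None = None
) -> tuple[SkeletonTimeSeries, NormalizationInfo]:
    """Apply the full chain in its fixed order.

    interpolate -> smooth -> center -> size-normalize -> aspect-adjust ->
    invert y -> relative fingertips. Returns the processed series together
    with the normalization info used.
    """
    config = config or PreprocessConfig()
    out = interpolate_missing(series)
    out = smooth(out, config.sigma)
    out, info = normalize_position(out)
    out = normalize_size(out, info)
    out = adjust_aspect(out, config.aspect_ratio)
    out = invert_y(out)
    out = relative_fingertips(out)
    return out, info
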