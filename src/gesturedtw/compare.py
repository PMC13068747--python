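"""Pair-level gesture distances: hand selection and the mirror rule.

A gesture pair is compared on its gesturing hands only. The per-hand
distance is the mean of six per-keypoint alignment distances (wrist plus
five fingertips). Handedness of the two strokes decides which hands are
compared; one-handed pairs produced with opposite hands additionally get
the mirror rule: the second speaker's skeleton is flipped about the body
midline (x negated, left/right labels swapped) and the lower of the
original and flipped distances is adopted, matching how human observers
perceive mirrored gestures as similar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import dtw_open_begin_end, normalized_distance
from .landmarks import HAND_ROLES, mirror_name
from .segment import GestureClip
from .timeseries import SkeletonTimeSeries


@dataclass
class DistanceResult:
    """Distance between one gesture pair with its selection provenance."""

    pair_distance: float
    per_hand: dict = field(default_factory=dict)
    per_keypoint: dict = field(default_factory=dict)
    mirror_used: bool = False
    branch: str = ""
    n_frames_a: int = 0
    n_frames_b: int = 0


def mirror_flip(series: SkeletonTimeSeries) -> SkeletonTimeSeries:
    """Reflect a body-centered skeleton about the midline.

    Negates x and swaps left/right landmark labels, so a left-handed
    gesture becomes its right-handed mirror image. Requires
    position-normalized input (mid-torso at the origin); applying the
    flip twice restores the original series.
    """
    data = np.empty_like(series.data)
    for j, name in enumerate(series.landmark_names):
        src = series.landmark_index(mirror_name(name))
        data[:, j, :] = series.data[:, src, :]
    data[:, :, 0] *= -1.0
    return series.with_data(data)


def _trajectory(
    series: SkeletonTimeSeries, landmark: str, use_z: bool
) -> np.ndarray:
    traj = series.get(landmark)
    return traj if use_z else traj[:, :2]


def hand_distance(
    series_a: SkeletonTimeSeries,
    series_b: SkeletonTimeSeries,
    hand_a: str,
    hand_b: str,
    use_z: bool = False,
    symmetrize: bool = False,
) -> tuple[float, dict]:
    """Mean normalized alignment distance over one hand's six keypoints.

    The first series acts as the query, the second as the reference (the
    asymmetric pattern is directional); ``symmetrize`` averages both
    directions. Returns the per-hand mean and the per-keypoint values.
    """
    per_keypoint = {}
    for role in HAND_ROLES:
        ta = _trajectory(series_a, f"{hand_a}_{role}", use_z)
        tb = _trajectory(series_b, f"{hand_b}_{role}", use_z)
        res = dtw_open_begin_end(ta, tb)
        d = normalized_distance(res.cumulative_cost, res.n, res.m)
        if symmetrize:
            rev = dtw_open_begin_end(tb, ta)
            d = (d + normalized_distance(rev.cumulative_cost, rev.n, rev.m)) / 2.0
        per_keypoint[role] = d
    return float(np.mean(list(per_keypoint.values()))), per_keypoint


def adopt_mirror_candidate(
    original: float, flipped: float
) -> tuple[float, bool]:
    """The mirror rule's selection: keep the lower distance, ties favor
    the original orientation."""
    if flipped < original:
        return flipped, True
    return original, False


def mirrored_pair_distance(
    clip_a: GestureClip,
    clip_b: GestureClip,
    use_z: bool = False,
    symmetrize: bool = False,
) -> DistanceResult:
    """Cross-hand distance with the mirror rule for opposite-handed pairs.

    Computes the distance between A's gesturing hand and B's gesturing
    hand, then again with B's skeleton mirror-flipped (after which B's
    gesturing hand carries A's label), and adopts the minimum.
    """
    ha, hb = clip_a.handedness, clip_b.handedness
    if "both" in (ha, hb) or ha == hb:
        raise ValueError(
            "mirror rule applies only to one-handed pairs produced with "
            f"opposite hands (got {ha!r} vs {hb!r})"
        )
    original, pk_orig = hand_distance(
        clip_a.series, clip_b.series, ha, hb, use_z, symmetrize
    )
    flipped_series = mirror_flip(clip_b.series)
    flipped, pk_flip = hand_distance(
        clip_a.series, flipped_series, ha, ha, use_z, symmetrize
    )
    adopted, used = adopt_mirror_candidate(original, flipped)
    key = f"{ha}|{hb}" if not used else f"{ha}|{hb}-flipped"
    return DistanceResult(
        pair_distance=adopted,
        per_hand={key: adopted},
        per_keypoint={key: pk_flip if used else pk_orig},
        mirror_used=used,
        branch="one-handed-opposite",
        n_frames_a=clip_a.n_frames,
        n_frames_b=clip_b.n_frames,
    )


def pair_distance(
    clip_a: GestureClip,
    clip_b: GestureClip,
    use_z: bool = False,
    mirror: bool = True,
    symmetrize: bool = False,
) -> DistanceResult:
    """Distance between a referentially aligned gesture pair.

    Hand selection: two-handed vs two-handed averages the left-left and
    right-right distances; same-handed one-handed pairs use that hand;
    opposite-handed one-handed pairs compare across hands and (with
    ``mirror`` on) apply the mirror rule; a one-handed vs two-handed pair
    takes the minimum over the single hand paired with each of the other
    speaker's hands.
    """
    ha, hb = clip_a.handedness, clip_b.handedness
    a, b = clip_a.series, clip_b.series

    def _hand(x, y, hx, hy):
        return hand_distance(x, y, hx, hy, use_z, symmetrize)

    if ha == "both" and hb == "both":
        per_hand, per_kp = {}, {}
        for side in ("left", "right"):
            d, pk = _hand(a, b, side, side)
            per_hand[f"{side}|{side}"] = d
            per_kp[f"{side}|{side}"] = pk
        result = DistanceResult(
            pair_distance=float(np.mean(list(per_hand.values()))),
            per_hand=per_hand,
            per_keypoint=per_kp,
            branch="both-both",
        )
    elif ha == hb:  # same single hand
        d, pk = _hand(a, b, ha, hb)
        result = DistanceResult(
            pair_distance=d,
            per_hand={f"{ha}|{hb}": d},
            per_keypoint={f"{ha}|{hb}": pk},
            branch="one-handed-same",
        )
    elif "both" not in (ha, hb):  # opposite single hands
        if mirror:
            result = mirrored_pair_distance(clip_a, clip_b, use_z, symmetrize)
        else:
            d, pk = _hand(a, b, ha, hb)
            result = DistanceResult(
                pair_distance=d,
                per_hand={f"{ha}|{hb}": d},
                per_keypoint={f"{ha}|{hb}": pk},
                branch="one-handed-opposite",
            )
    else:  # one hand vs both hands
        single_on_a = hb == "both"
        single = ha if single_on_a else hb
        per_hand, per_kp = {}, {}
        for side in ("left", "right"):
            hx, hy = (single, side) if single_on_a else (side, hb)
            d, pk = _hand(a, b, hx, hy)
            per_hand[f"{hx}|{hy}"] = d
            per_kp[f"{hx}|{hy}"] = pk
        best = min(per_hand, key=per_hand.get)
        result = DistanceResult(
            pair_distance=per_hand[best],
            per_hand=per_hand,
            per_keypoint=per_kp,
            branch="one-vs-two",
        )
    result.n_frames_a = clip_a.n_frames
    result.n_frames_b = clip_b.n_frames
    return result
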