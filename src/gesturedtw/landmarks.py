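"""Canonical landmark vocabulary for the tracked skeleton.

The pipeline works on a reduced MediaPipe-style skeleton: both wrists, the
five fingertips of each hand, and the four torso anchors (shoulders and
hips) used for position and size normalization. Coordinates are normalized
image units (0-1 per axis, y increasing downward, z a monocular depth
heuristic) until the preprocessing chain re-expresses them in body-centered
units.
"""

from __future__ import annotations

SIDES = ("left", "right")

FINGERTIPS = ("thumb_tip", "index_tip", "middle_tip", "ring_tip", "pinky_tip")

#: keypoint roles entering the distance computation, per hand
HAND_ROLES = ("wrist",) + FINGERTIPS

TORSO = (
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
)

#: full canonical landmark order: torso, then left hand, then right hand
LANDMARKS = TORSO + tuple(
    f"{side}_{role}" for side in SIDES for role in HAND_ROLES
)

AXES = ("x", "y", "z")


def hand_landmarks(side: str) -> tuple[str, ...]:
    """The six distance-relevant landmarks of one hand, wrist first."""
    if side not in SIDES:
        raise ValueError(f"unknown hand side: {side!r}")
    return tuple(f"{side}_{role}" for role in HAND_ROLES)


def mirror_name(name: str) -> str:
    """Swap the left/right prefix of a landmark name (identity otherwise)."""
    if name.startswith("left_"):
        return "right_" + name[5:]
    if name.startswith("right_"):
        return "left_" + name[6:]
    return name
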