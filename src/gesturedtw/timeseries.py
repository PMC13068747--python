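"""Containers for skeleton keypoint time series and gesture annotations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .landmarks import LANDMARKS

_VALID_HANDEDNESS = frozenset({"left", "right", "both"})


@dataclass
class SkeletonTimeSeries:
    """Per-frame 3D keypoint coordinates for one recording.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, n_landmarks, 3)``; NaN marks a missing
        coordinate. Values must otherwise be finite.
    landmark_names
        One name per landmark, matching ``data``'s second axis.
    fps
        Frames per second (> 0).
    speaker_id, recording_id
        Opaque labels carried through the pipeline.
    """

    data: np.ndarray
    landmark_names: tuple[str, ...] = LANDMARKS
    fps: float = 30.0
    speaker_id: str = ""
    recording_id: str = ""
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("data must have shape (n_frames, n_landmarks, 3)")
        if self.data.shape[0] < 1:
            raise ValueError("series must contain at least one frame")
        if self.data.shape[1] != len(self.landmark_names):
            raise ValueError("landmark_names length does not match data")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if np.isinf(self.data).any():
            raise ValueError("coordinates must be finite or NaN")
        self.landmark_names = tuple(self.landmark_names)
        self._index = {n: i for i, n in enumerate(self.landmark_names)}

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def landmark_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"landmark {name!r} not in series") from None

    def get(self, name: str) -> np.ndarray:
        """Trajectory of one landmark, shape ``(n_frames, 3)``."""
        return self.data[:, self.landmark_index(name), :]

    def with_data(self, data: np.ndarray) -> "SkeletonTimeSeries":
        """Copy of this series with new coordinate data."""
        return replace(self, data=np.asarray(data, dtype=float))

    def slice_frames(self, start: int, stop: int) -> "SkeletonTimeSeries":
        if not (0 <= start < stop <= self.n_frames):
            raise IndexError(
                f"frame window [{start}, {stop}) outside recording of "
                f"{self.n_frames} frames"
            )
        return self.with_data(self.data[start:stop].copy())

    def copy(self) -> "SkeletonTimeSeries":
        return self.with_data(self.data.copy())


@dataclass(frozen=True)
class GestureSegment:
    """One manually annotated gesture stroke."""

    dyad_id: str
    speaker_id: str
    trial_id: str
    t_start: float
    t_end: float
    handedness: str

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValueError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )
        if self.handedness not in _VALID_HANDEDNESS:
            raise ValueError(
                f"handedness must be one of {sorted(_VALID_HANDEDNESS)}, "
                f"got {self.handedness!r}"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


FEATURES = ("handshape", "movement", "orientation", "position")


@dataclass(frozen=True)
class SimilarityAnnotation:
    """Human similarity coding of one gesture pair.

    ``ratings`` maps each of the four form features (handshape, movement,
    orientation, position) to a value: binary {0,1} or ordinal 0-5
    depending on ``scale``. Handedness match is kept separately because the
    distance computation already restricts itself to gesturing hands.
    """

    ratings: dict
    scale: str = "binary"
    handedness_match: int | None = None

    def __post_init__(self):
        if set(self.ratings) != set(FEATURES):
            raise ValueError(
                f"ratings must cover exactly the features {FEATURES}"
            )
        allowed = {0, 1} if self.scale == "binary" else set(range(6))
        if self.scale not in ("binary", "ordinal6"):
            raise ValueError(f"unknown scale {self.scale!r}")
        for feat, val in self.ratings.items():
            if val not in allowed:
                raise ValueError(
                    f"rating {val!r} for {feat} invalid on scale {self.scale}"
                )
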