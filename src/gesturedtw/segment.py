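"""Extraction of per-gesture clips from annotated stroke windows.

Stroke annotations give start/end times in seconds; frames are selected
with a half-open ``[round(t_start*fps), round(t_end*fps))`` window. Very
short strokes produce unreliable alignment distances, so clips under a
minimum duration (330 ms by default, i.e. ten frames at 30 FPS) are
lengthened by borrowing real frames from the surrounding recording,
split as evenly as possible before and after the stroke.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .timeseries import GestureSegment, SkeletonTimeSeries

DEFAULT_MIN_MS = 330.0


def min_frames(fps: float, min_ms: float = DEFAULT_MIN_MS) -> int:
    """Minimum clip length in frames at a given frame rate (ceiling)."""
    return math.ceil(min_ms / 1000.0 * fps)


@dataclass
class GestureClip:
    """One gesture stroke's time series, possibly padded to the minimum."""

    segment: GestureSegment
    series: SkeletonTimeSeries
    start_frame: int
    end_frame: int
    padded: bool = False
    pad_before: int = 0
    pad_after: int = 0

    @property
    def n_frames(self) -> int:
        return self.series.n_frames

    @property
    def handedness(self) -> str:
        return self.segment.handedness


def frame_window(segment: GestureSegment, fps: float) -> tuple[int, int]:
    """Half-open 0-based frame window for a stroke at the given FPS."""
    return round(segment.t_start * fps), round(segment.t_end * fps)


def extract_clip(
    series: SkeletonTimeSeries,
    segment: GestureSegment,
    min_ms: float = DEFAULT_MIN_MS,
) -> GestureClip:
    """Cut the stroke window out of a recording and enforce the minimum.

    Raises ``IndexError`` when the window falls outside the recording.
    """
    start, end = frame_window(segment, series.fps)
    if start < 0 or end > series.n_frames or start >= end:
        raise IndexError(
            f"stroke window [{start}, {end}) outside recording "
            f"{series.recording_id!r} of {series.n_frames} frames"
        )
    clip = GestureClip(
        segment=segment,
        series=series.slice_frames(start, end),
        start_frame=start,
        end_frame=end,
    )
    return pad_to_minimum(clip, series, min_ms=min_ms)


def pad_to_minimum(
    clip: GestureClip,
    full_series: SkeletonTimeSeries,
    min_ms: float = DEFAULT_MIN_MS,
) -> GestureClip:
    """Lengthen a short clip with surrounding frames of its recording.

    The frame deficit is split evenly before/after the stroke; an odd
    deficit puts the extra frame after. If one side hits the recording
    boundary, the remainder is borrowed from the other side. Padding only
    ever uses frames that exist in the source recording.
    """
    need = min_frames(full_series.fps, min_ms)
    deficit = need - clip.n_frames
    if deficit <= 0:
        return clip
    total = full_series.n_frames
    if total < need:
        raise ValueError(
            f"recording {full_series.recording_id!r} has {total} frames, "
            f"shorter than the {need}-frame minimum"
        )
    before = deficit // 2
    after = deficit - before
    start = clip.start_frame - before
    end = clip.end_frame + after
    if start < 0:  # hit the left boundary: spill remainder to the right
        end += -start
        start = 0
    if end > total:  # hit the right boundary: spill remainder to the left
        start -= end - total
        end = total
    return GestureClip(
        segment=clip.segment,
        series=full_series.slice_frames(start, end),
        start_frame=start,
        end_frame=end,
        padded=True,
        pad_before=clip.start_frame - start,
        pad_after=end - clip.end_frame,
    )
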