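"""Readers and writers for the pipeline's plain-text table formats.

Keypoint time series travel as wide CSV (one row per frame, columns
``<landmark>_x|_y|_z``), gesture strokes as ELAN-style TSV exports,
annotations and distance outputs as CSV. Empty cells denote missing
coordinates and survive round-trips as missing, never as zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landmarks import AXES, LANDMARKS
from .timeseries import FEATURES, GestureSegment, SimilarityAnnotation, SkeletonTimeSeries


class FormatError(ValueError):
    """A file does not conform to the expected table layout."""


SEGMENT_COLUMNS = ("dyad", "speaker", "trial", "t_start", "t_end", "handedness")

DISTANCE_META_COLUMNS = (
    "pair_id",
    "pair_distance",
    "mirror_used",
    "n_frames_a",
    "n_frames_b",
)


def read_keypoint_timeseries(
    path,
    fps: float,
    landmark_names: tuple[str, ...] = LANDMARKS,
    speaker_id: str = "",
    recording_id: str = "",
) -> SkeletonTimeSeries:
    """Load a wide keypoint CSV into a :class:`SkeletonTimeSeries`.

    Unparseable or empty cells become NaN (missing). Raises
    :class:`FormatError` naming the first absent landmark column set.
    """
    if not fps > 0:
        raise ValueError(f"fps must be positive, got {fps}")
    frame = pd.read_csv(path)
    for name in landmark_names:
        for axis in AXES:
            if f"{name}_{axis}" not in frame.columns:
                raise FormatError(
                    f"keypoint file {path} lacks column {name}_{axis}"
                )
    n = len(frame)
    if n < 1:
        raise FormatError(f"keypoint file {path} contains no frames")
    data = np.empty((n, len(landmark_names), 3))
    for j, name in enumerate(landmark_names):
        for k, axis in enumerate(AXES):
            col = pd.to_numeric(frame[f"{name}_{axis}"], errors="coerce")
            data[:, j, k] = col.to_numpy(dtype=float)
    return SkeletonTimeSeries(
        data=data,
        landmark_names=landmark_names,
        fps=fps,
        speaker_id=speaker_id,
        recording_id=recording_id,
    )


def write_keypoint_timeseries(series: SkeletonTimeSeries, path) -> None:
    """Write a series to the wide CSV dialect (NaN as empty cells)."""
    cols = {}
    for j, name in enumerate(series.landmark_names):
        for k, axis in enumerate(AXES):
            cols[f"{name}_{axis}"] = series.data[:, j, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_segment_table(path) -> list[GestureSegment]:
    """Parse a gesture-stroke TSV export into :class:`GestureSegment` rows."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SEGMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"segment table {path} lacks columns {missing}")
    segments = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            segments.append(
                GestureSegment(
                    dyad_id=str(row.dyad),
                    speaker_id=str(row.speaker),
                    trial_id=str(row.trial),
                    t_start=float(row.t_start),
                    t_end=float(row.t_end),
                    handedness=str(row.handedness),
                )
            )
        except ValueError as exc:
            raise FormatError(f"segment table row {row_no}: {exc}") from exc
    return segments


def write_segment_table(segments: list[GestureSegment], path) -> None:
    pd.DataFrame(
        [
            {
                "dyad": s.dyad_id,
                "speaker": s.speaker_id,
                "trial": s.trial_id,
                "t_start": s.t_start,
                "t_end": s.t_end,
                "handedness": s.handedness,
            }
            for s in segments
        ],
        columns=list(SEGMENT_COLUMNS),
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_annotation_table(path) -> dict[str, SimilarityAnnotation]:
    """Read per-pair feature similarity ratings keyed by pair id.

    Expects columns ``pair_id``, the four feature columns, optionally
    ``scale`` and ``handedness_match``.
    """
    frame = pd.read_csv(path)
    missing = [c for c in ("pair_id",) + FEATURES if c not in frame.columns]
    if missing:
        raise FormatError(f"annotation table {path} lacks columns {missing}")
    out = {}
    for row in frame.itertuples(index=False):
        scale = getattr(row, "scale", "binary")
        hm = getattr(row, "handedness_match", None)
        out[str(row.pair_id)] = SimilarityAnnotation(
            ratings={f: int(getattr(row, f)) for f in FEATURES},
            scale=str(scale),
            handedness_match=None if hm is None or pd.isna(hm) else int(hm),
        )
    return out


def write_annotation_table(
    annotations: dict[str, SimilarityAnnotation], path
) -> None:
    rows = []
    for pair_id, ann in annotations.items():
        row = {"pair_id": pair_id, "scale": ann.scale}
        row.update({f: ann.ratings[f] for f in FEATURES})
        if ann.handedness_match is not None:
            row["handedness_match"] = ann.handedness_match
        rows.append(row)
    cols = ["pair_id", *FEATURES, "scale"]
    if any("handedness_match" in r for r in rows):
        cols.append("handedness_match")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_distance_table(table: pd.DataFrame, path) -> None:
    """Write per-pair distance results with a stable column order."""
    meta = [c for c in DISTANCE_META_COLUMNS if c in table.columns]
    rest = sorted(c for c in table.columns if c not in meta)
    table.loc[:, meta + rest].to_csv(path, index=False, float_format="%.12g")


def read_distance_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in DISTANCE_META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"distance table {path} lacks columns {missing}")
    return frame
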