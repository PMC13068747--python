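"""End-to-end orchestration: preprocess, segment, compare, validate.

Recordings are keyed ``<dyad>_<trial>_<speaker>``; the two gesture
strokes annotated for the same dyad and trial form a referentially
aligned pair whose id is ``<dyad>_<trial>``. The runner preprocesses
each recording once, extracts stroke clips, computes pair distances with
the configured hand-selection and mirror options, and assembles the
distance table consumed by the validation statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .compare import pair_distance
from .preprocess import PreprocessConfig, run_pipeline
from .segment import DEFAULT_MIN_MS, extract_clip
from .timeseries import GestureSegment, SkeletonTimeSeries

log = logging.getLogger("gesturedtw")


@dataclass
class RunConfig:
    """Options of one reproducible pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    min_ms: float = DEFAULT_MIN_MS
    mirror: bool = True
    symmetrize: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        pp = {
            k: raw[k] for k in ("sigma", "aspect_ratio", "use_z") if k in raw
        }
        opts = {
            k: raw[k]
            for k in ("min_ms", "mirror", "symmetrize", "seed")
            if k in raw
        }
        return cls(preprocess=PreprocessConfig(**pp), **opts)


def recording_id_for(segment: GestureSegment) -> str:
    return f"{segment.dyad_id}_{segment.trial_id}_{segment.speaker_id}"


def pair_id_for(segment: GestureSegment) -> str:
    return f"{segment.dyad_id}_{segment.trial_id}"


def compute_distance_table(
    recordings: dict[str, SkeletonTimeSeries],
    segments: list[GestureSegment],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Distance table over all referentially aligned pairs.

    Each recording is preprocessed once; pairs are the (dyad, trial)
    groups containing exactly two speakers' strokes. The table carries
    the adopted comparison's per-keypoint distances (``kp_*`` columns),
    per-hand means (``hand_*`` columns), the selection branch and the
    mirror flag.
    """
    config = config or RunConfig()
    processed: dict[str, SkeletonTimeSeries] = {}
    for rid, series in recordings.items():
        processed[rid], _ = run_pipeline(series, config.preprocess)

    by_pair: dict[str, list[GestureSegment]] = {}
    for seg in segments:
        by_pair.setdefault(pair_id_for(seg), []).append(seg)

    rows = []
    for pair_id, segs in by_pair.items():
        if len(segs) != 2:
            raise ValueError(
                f"pair {pair_id!r} has {len(segs)} strokes; expected 2"
            )
        seg_a, seg_b = sorted(segs, key=lambda s: s.speaker_id)
        clips = []
        for seg in (seg_a, seg_b):
            rid = recording_id_for(seg)
            if rid not in processed:
                raise KeyError(f"pair {pair_id!r}: recording {rid!r} missing")
            clips.append(extract_clip(processed[rid], seg, min_ms=config.min_ms))
        result = pair_distance(
            clips[0],
            clips[1],
            use_z=config.preprocess.use_z,
            mirror=config.mirror,
            symmetrize=config.symmetrize,
        )
        log.debug(
            "pair %s: branch=%s mirror_used=%s distance=%.4f",
            pair_id, result.branch, result.mirror_used, result.pair_distance,
        )
        row = {
            "pair_id": pair_id,
            "pair_distance": result.pair_distance,
            "mirror_used": result.mirror_used,
            "n_frames_a": result.n_frames_a,
            "n_frames_b": result.n_frames_b,
            "dyad": seg_a.dyad_id,
            "item": seg_a.trial_id,
            "branch": result.branch,
            "handedness_a": seg_a.handedness,
            "handedness_b": seg_b.handedness,
        }
        for key, value in result.per_hand.items():
            row[f"hand_{key.replace('|', '_')}"] = value
        for key, per_kp in result.per_keypoint.items():
            for role, value in per_kp.items():
                row[f"kp_{key.replace('|', '_')}_{role}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
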