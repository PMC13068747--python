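"""Synthetic dyadic gesture corpora with ground-truth form similarity.

The generator emulates what a video-based tracker emits for a seated
speaker: normalized image coordinates (0-1, y down), a roughly static
torso with slight sway, a resting hand near the hip, and a gesturing hand
whose wrist follows a parametric stroke trajectory while the fingertips
hold a rotated handshape template. Occlusion gaps (NaN runs) and
coordinate noise mimic tracker failure and jitter.

A gesture pair is a base gesture plus a partner gesture derived from the
same specification with zero or more form features perturbed — handshape
(template swap), movement (trajectory change), orientation (rotation of
the fingertip frame), position (anchor shift). Unperturbed features are
reproduced up to small natural jitter, giving every pair a ground-truth
per-feature similarity annotation in the style of human feature coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .landmarks import LANDMARKS, SIDES
from .timeseries import FEATURES, GestureSegment, SimilarityAnnotation, SkeletonTimeSeries

# -- committed perturbation magnitudes (see scripts/tune_magnitudes.py) -----
ORIENTATION_PERTURB = 1.3  # radians rotating the fingertip frame
POSITION_PERTURB = 0.18  # image units shifting the gesture anchor
MOVEMENT_DIRECTION_PERTURB = 1.0  # radians rotating the trajectory
# natural jitter of features reproduced as "similar"
ORIENTATION_JITTER = 0.08
POSITION_JITTER = 0.015

#: fingertip offsets (thumb, index, middle, ring, pinky) for a right hand,
#: image units relative to the wrist, before orientation rotation
HANDSHAPE_TEMPLATES: dict[str, np.ndarray] = {
    "fist": np.array(
        [[0.018, -0.006], [0.016, -0.014], [0.014, -0.016],
         [0.010, -0.016], [0.006, -0.014]]
    ),
    "open": np.array(
        [[0.035, -0.020], [0.022, -0.052], [0.004, -0.060],
         [-0.014, -0.054], [-0.028, -0.040]]
    ),
    "c_shape": np.array(
        [[0.040, 0.010], [0.046, -0.024], [0.040, -0.038],
         [0.030, -0.046], [0.018, -0.050]]
    ),
    "point": np.array(
        [[0.016, -0.008], [0.010, -0.062], [0.012, -0.018],
         [0.008, -0.016], [0.004, -0.014]]
    ),
    "pinch": np.array(
        [[0.036, -0.034], [0.038, -0.036], [0.012, -0.022],
         [0.008, -0.018], [0.004, -0.016]]
    ),
}

TRAJECTORY_KINDS = ("line", "arc", "circle", "zigzag")

# static body layout in image coordinates (y down)
_BODY = {
    "left_shoulder": (0.39, 0.38),
    "right_shoulder": (0.61, 0.38),
    "left_hip": (0.42, 0.62),
    "right_hip": (0.58, 0.62),
}
_REST_WRIST = {"left": (0.37, 0.64), "right": (0.63, 0.64)}


@dataclass(frozen=True)
class GestureSpec:
    """Parametric description of one gesture stroke."""

    trajectory_kind: str = "line"
    amplitude: float = 0.12
    direction: float = 0.0
    center: tuple[float, float] = (0.5, 0.4)
    handshape_template: str = "open"
    orientation_angle: float = 0.0
    position_anchor: tuple[float, float] | None = None  # alias of center
    duration_ms: float = 800.0
    hand: str = "right"
    fps: float = 30.0
    mirrored: bool = False
    lead_s: float = 0.5

    def __post_init__(self):
        if self.trajectory_kind not in TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory {self.trajectory_kind!r}")
        if self.handshape_template not in HANDSHAPE_TEMPLATES:
            raise ValueError(f"unknown template {self.handshape_template!r}")
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be positive")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.hand not in ("left", "right", "both"):
            raise ValueError(f"invalid hand {self.hand!r}")


@dataclass(frozen=True)
class PairSpec:
    """A base gesture plus per-feature perturbation instructions."""

    base: GestureSpec
    perturb: dict = field(default_factory=dict)  # feature -> magnitude >= 0
    mirror: bool = False
    noise_sd: float = 0.008
    occlusion_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.perturb) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown perturbation features {sorted(unknown)}")
        if any(m < 0 for m in self.perturb.values()):
            raise ValueError("perturbation magnitudes must be >= 0")
        if not 0 <= self.occlusion_rate < 1:
            raise ValueError("occlusion_rate must be in [0, 1)")


def _ease(u: np.ndarray) -> np.ndarray:
    """Smoothstep velocity profile for stroke progress."""
    return 3 * u**2 - 2 * u**3


def _wrist_path(spec: GestureSpec, n: int) -> np.ndarray:
    """Stroke trajectory of the gesturing wrist, shape (n, 2)."""
    u = _ease(np.linspace(0.0, 1.0, n))
    cx, cy = spec.center
    a = spec.amplitude
    d = spec.direction
    ux, uy = math.cos(d), math.sin(d)
    px, py = -uy, ux  # perpendicular
    if spec.trajectory_kind == "line":
        s = (u - 0.5) * a
        x, y = cx + s * ux, cy + s * uy
    elif spec.trajectory_kind == "arc":
        ang = math.pi * u
        x = cx - (a / 2) * np.cos(ang) * ux + (a / 2) * np.sin(ang) * px
        y = cy - (a / 2) * np.cos(ang) * uy + (a / 2) * np.sin(ang) * py
    elif spec.trajectory_kind == "circle":
        ang = 2 * math.pi * u + d
        x = cx + (a / 2) * np.cos(ang)
        y = cy + (a / 2) * np.sin(ang)
    else:  # zigzag: triangle wave across the direction axis
        s = (u - 0.5) * a
        zig = (a / 4) * (2 * np.abs(2 * ((3 * u) % 1) - 1) - 1)
        x = cx + s * ux + zig * px
        y = cy + s * uy + zig * py
    return np.column_stack([x, y])


def _tip_offsets(spec: GestureSpec, side: str) -> np.ndarray:
    """Rotated handshape offsets for one hand, shape (5, 2).

    Templates describe a right hand; left-hand offsets use the x-mirrored
    template rotated by the same orientation angle.
    """
    offs = HANDSHAPE_TEMPLATES[spec.handshape_template].copy()
    if side == "left":
        offs[:, 0] *= -1.0
    ang = spec.orientation_angle
    rot = np.array(
        [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
    )
    return offs @ rot.T


def mirror_series(series: SkeletonTimeSeries) -> SkeletonTimeSeries:
    """Exact midline reflection of a rendered recording.

    Reflects x about the image center (x -> 1 - x) and swaps left/right
    landmark labels, producing the mirror-image production of the same
    gesture by the opposite hand. NaN gaps are preserved.
    """
    from .landmarks import mirror_name

    data = np.empty_like(series.data)
    index = {n: i for i, n in enumerate(series.landmark_names)}
    for j, name in enumerate(series.landmark_names):
        data[:, j, :] = series.data[:, index[mirror_name(name)], :]
    data[:, :, 0] = 1.0 - data[:, :, 0]
    return series.with_data(data)


def stroke_window_s(spec: GestureSpec) -> tuple[float, float]:
    """Stroke start/end in seconds within the rendered recording."""
    return spec.lead_s, spec.lead_s + spec.duration_ms / 1000.0


def render_gesture(
    spec: GestureSpec,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    occlusion_rate: float = 0.0,
    speaker_id: str = "",
    recording_id: str = "",
) -> SkeletonTimeSeries:
    """Render a full recording: rest, stroke, rest.

    Torso landmarks are static up to a small sway; the gesturing wrist
    eases from its rest position into the stroke trajectory and back; the
    fingertips ride on the wrist with the rotated handshape offsets.
    """
    fps = spec.fps
    n_lead = max(2, round(spec.lead_s * fps))
    n_stroke = max(2, round(spec.duration_ms / 1000.0 * fps))
    n = 2 * n_lead + n_stroke
    t = np.arange(n) / fps

    data = np.zeros((n, len(LANDMARKS), 3))
    index = {name: i for i, name in enumerate(LANDMARKS)}

    sway = 0.004 * np.sin(2 * math.pi * 0.3 * t)
    for name, (bx, by) in _BODY.items():
        data[:, index[name], 0] = bx + sway
        data[:, index[name], 1] = by
        data[:, index[name], 2] = 0.02 * rng.standard_normal()

    def _gesturing_geometry(side: str):
        """Wrist (n, 2) and tips (n, 5, 2) for one gesturing hand."""
        rest = np.array(_REST_WRIST[side])
        wrist = np.empty((n, 2))
        path = _wrist_path(spec, n_stroke)
        wrist[n_lead:n_lead + n_stroke] = path
        # ease in/out between rest and the stroke end points
        ease_in = _ease(np.linspace(0, 1, n_lead))[:, None]
        wrist[:n_lead] = rest + ease_in * (path[0] - rest)
        ease_out = _ease(np.linspace(1, 0, n_lead))[:, None]
        wrist[n_lead + n_stroke:] = rest + ease_out * (path[-1] - rest)
        tips = wrist[:, None, :] + _tip_offsets(spec, side)[None, :, :]
        return wrist, tips

    primary = "right" if spec.hand == "both" else spec.hand
    wrists: dict[str, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}
    wrists[primary], tips[primary] = _gesturing_geometry(primary)
    other = "left" if primary == "right" else "right"
    if spec.hand == "both":
        # symmetric two-handed gesture: exact midline reflection
        wrists[other] = wrists[primary].copy()
        wrists[other][:, 0] = 1.0 - wrists[other][:, 0]
        tips[other] = tips[primary].copy()
        tips[other][:, :, 0] = 1.0 - tips[other][:, :, 0]
    else:
        rest = np.array(_REST_WRIST[other])
        wrists[other] = np.tile(rest, (n, 1)).astype(float)
        rest_offs = _tip_offsets(
            replace(spec, orientation_angle=0.0, handshape_template="fist"),
            other,
        )
        tips[other] = wrists[other][:, None, :] + rest_offs[None, :, :]

    for side in SIDES:
        data[:, index[f"{side}_wrist"], :2] = wrists[side]
        data[:, index[f"{side}_wrist"], 2] = 0.0
        for k, tip in enumerate(
            ("thumb_tip", "index_tip", "middle_tip", "ring_tip", "pinky_tip")
        ):
            data[:, index[f"{side}_{tip}"], :2] = tips[side][:, k, :]
            data[:, index[f"{side}_{tip}"], 2] = -0.01

    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    if occlusion_rate > 0:
        data = _inject_occlusion(data, occlusion_rate, rng)

    return SkeletonTimeSeries(
        data=data,
        landmark_names=LANDMARKS,
        fps=fps,
        speaker_id=speaker_id,
        recording_id=recording_id,
    )


def _inject_occlusion(
    data: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """NaN out short runs per landmark track, never a whole track."""
    n = data.shape[0]
    out = data.copy()
    for j in range(data.shape[1]):
        if rng.random() >= min(1.0, rate * 4):  # most tracks stay clean
            continue
        gap = int(rng.integers(1, max(2, int(rate * n) + 2)))
        start = int(rng.integers(1, max(2, n - gap)))  # keep frame 0 observed
        stop = min(start + gap, n - 1)  # keep the last frame observed
        out[start:stop, j, :] = np.nan
    return out


def perturb_spec(
    base: GestureSpec, perturb: dict, rng: np.random.Generator
) -> GestureSpec:
    """Derive the partner gesture's spec from the base.

    Perturbed features change categorically (handshape, movement) or by
    the committed magnitudes (orientation, position); unperturbed ones
    are reproduced up to small natural jitter.
    """
    spec = base
    # natural jitter applied to every partner gesture
    jitter_ang = float(rng.normal(0.0, ORIENTATION_JITTER))
    jitter_pos = rng.normal(0.0, POSITION_JITTER, size=2)
    cx, cy = spec.center
    spec = replace(
        spec,
        orientation_angle=spec.orientation_angle + jitter_ang,
        center=(cx + float(jitter_pos[0]), cy + float(jitter_pos[1])),
        amplitude=spec.amplitude * float(rng.uniform(0.92, 1.08)),
        duration_ms=spec.duration_ms * float(rng.uniform(0.9, 1.1)),
    )
    if "handshape" in perturb:
        others = [t for t in HANDSHAPE_TEMPLATES if t != base.handshape_template]
        spec = replace(spec, handshape_template=str(rng.choice(others)))
    if "movement" in perturb:
        others = [k for k in TRAJECTORY_KINDS if k != base.trajectory_kind]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        spec = replace(
            spec,
            trajectory_kind=str(rng.choice(others)),
            direction=spec.direction
            + sign * MOVEMENT_DIRECTION_PERTURB * perturb["movement"],
        )
    if "orientation" in perturb:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        spec = replace(
            spec,
            orientation_angle=spec.orientation_angle
            + sign * ORIENTATION_PERTURB * perturb["orientation"],
        )
    if "position" in perturb:
        ang = float(rng.uniform(0.0, 2 * math.pi))
        shift = POSITION_PERTURB * perturb["position"]
        cx, cy = spec.center
        spec = replace(
            spec, center=(cx + shift * math.cos(ang), cy + shift * math.sin(ang))
        )
    return spec


def render_pair(
    pairspec: PairSpec,
) -> tuple[SkeletonTimeSeries, SkeletonTimeSeries, SimilarityAnnotation]:
    """Render both speakers' recordings plus the ground-truth annotation."""
    rng = np.random.default_rng(pairspec.seed)
    spec_a = pairspec.base
    spec_b = perturb_spec(spec_a, pairspec.perturb, rng)
    if pairspec.mirror and spec_a.hand == "both":
        raise ValueError("mirrored pairs require one-handed gestures")
    series_a = render_gesture(
        spec_a, rng, pairspec.noise_sd, pairspec.occlusion_rate, "A"
    )
    series_b = render_gesture(
        spec_b, rng, pairspec.noise_sd, pairspec.occlusion_rate, "B"
    )
    if pairspec.mirror:
        series_b = mirror_series(series_b)
    ratings = {
        f: 0 if pairspec.perturb.get(f, 0) > 0 else 1 for f in FEATURES
    }
    hand_b = spec_b.hand
    if pairspec.mirror:
        hand_b = "left" if hand_b == "right" else "right"
    annotation = SimilarityAnnotation(
        ratings=ratings,
        scale="binary",
        handedness_match=int(spec_a.hand == hand_b),
    )
    return series_a, series_b, annotation


@dataclass
class Corpus:
    """An in-memory synthetic corpus ready for the full pipeline."""

    recordings: dict  # recording_id -> SkeletonTimeSeries
    segments: list  # GestureSegment, recording_id = dyad_trial_speaker
    annotations: dict  # pair_id -> SimilarityAnnotation
    truth: dict  # pair_id -> {"perturbed": [...], "mirror": bool, ...}
    fps: float


def _random_spec(rng: np.random.Generator, fps: float) -> GestureSpec:
    hand = str(rng.choice(["left", "right", "both"], p=[0.35, 0.35, 0.30]))
    return GestureSpec(
        trajectory_kind=str(rng.choice(TRAJECTORY_KINDS)),
        amplitude=float(rng.uniform(0.08, 0.16)),
        direction=float(rng.uniform(0.0, 2 * math.pi)),
        center=(float(rng.uniform(0.3, 0.7)), float(rng.uniform(0.22, 0.5))),
        handshape_template=str(rng.choice(list(HANDSHAPE_TEMPLATES))),
        orientation_angle=float(rng.uniform(-math.pi, math.pi)),
        duration_ms=float(rng.uniform(260.0, 1500.0)),
        hand=hand,
        fps=fps,
    )


def generate_corpus(
    n_pairs: int,
    n_dyads: int = 8,
    n_items: int = 16,
    seed: int = 0,
    fps: float = 30.0,
    perturb_prob: float = 0.25,
    mirror_prob: float = 0.2,
    noise_sd: float = 0.008,
    occlusion_rate: float = 0.05,
) -> Corpus:
    """Generate a dyadic corpus of referentially aligned gesture pairs.

    Each pair belongs to a dyad and an item (the pair id is
    ``<dyad>_<trial>``); each speaker's gesture is rendered as its own
    recording whose id is ``<dyad>_<trial>_<speaker>``. Per-feature
    perturbation flags are Bernoulli(``perturb_prob``), which calibrates
    the proportion of feature ratings marked similar to about
    1 - perturb_prob; the first five pairs are forced to span all overlap
    counts 0-4 so every similarity level occurs in any corpus. One-handed
    pairs become mirrored productions with probability ``mirror_prob``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    recordings: dict[str, SkeletonTimeSeries] = {}
    segments: list[GestureSegment] = []
    annotations: dict[str, SimilarityAnnotation] = {}
    truth: dict[str, dict] = {}

    for i in range(n_pairs):
        dyad = f"d{i % n_dyads:02d}"
        item = f"i{(i // n_dyads) % n_items:02d}"
        rep = i // (n_dyads * n_items)
        trial = f"{item}r{rep}" if rep else item
        pair_id = f"{dyad}_{trial}"

        if i < 5:  # guarantee coverage of all overlap counts 0..4
            n_perturbed = 4 - i
            flags = rng.permutation(
                [1] * n_perturbed + [0] * (4 - n_perturbed)
            )
        else:
            flags = (rng.random(4) < perturb_prob).astype(int)
        perturb = {f: 1.0 for f, on in zip(FEATURES, flags) if on}

        base = _random_spec(rng, fps)
        mirror = bool(base.hand != "both" and rng.random() < mirror_prob)
        pairspec = PairSpec(
            base=base,
            perturb=perturb,
            mirror=mirror,
            noise_sd=noise_sd,
            occlusion_rate=occlusion_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series_a, series_b, annotation = render_pair(pairspec)
        spec_b_hand = (
            ("left" if base.hand == "right" else "right") if mirror else base.hand
        )
        # B's stroke duration may jitter; recover it from the rendered length
        for speaker, series, hand in (
            ("A", series_a, base.hand),
            ("B", series_b, spec_b_hand),
        ):
            rid = f"{pair_id}_{speaker}"
            recordings[rid] = replace(
                series, speaker_id=speaker, recording_id=rid
            )
            n_lead = max(2, round(base.lead_s * fps))
            n_stroke = series.n_frames - 2 * n_lead
            segments.append(
                GestureSegment(
                    dyad_id=dyad,
                    speaker_id=speaker,
                    trial_id=trial,
                    t_start=n_lead / fps,
                    t_end=(n_lead + n_stroke) / fps,
                    handedness=hand,
                )
            )
        annotations[pair_id] = annotation
        truth[pair_id] = {
            "perturbed": sorted(perturb),
            "mirror": mirror,
            "overlap": int(sum(annotation.ratings.values())),
            "hand_a": base.hand,
            "hand_b": spec_b_hand,
        }

    return Corpus(
        recordings=recordings,
        segments=segments,
        annotations=annotations,
        truth=truth,
        fps=fps,
    )
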