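import itertools

import numpy as np
import pytest

from gesturedtw.landmarks import LANDMARKS
from gesturedtw.preprocess import run_pipeline
from gesturedtw.segment import extract_clip
from gesturedtw.synthetic import GestureSpec, render_gesture
from gesturedtw.timeseries import GestureSegment, SkeletonTimeSeries


def brute_force_obe_cost(cost_matrix: np.ndarray) -> float:
    """Exhaustive minimum over all admissible open-begin-end paths.

    Enumerates every reference-increment sequence in {1, 0, 2}^(n-1) and
    every entry point, evaluating each path's summed local cost directly.
    Independent of the dynamic program it checks.
    """
    C = np.asarray(cost_matrix, dtype=float)
    n, m = C.shape
    deltas = np.array(
        list(itertools.product((1, 0, 2), repeat=n - 1)), dtype=int
    )
    cum = np.concatenate(
        [np.zeros((len(deltas), 1), dtype=int), np.cumsum(deltas, axis=1)],
        axis=1,
    )
    best = np.inf
    for j0 in range(m):
        j = j0 + cum
        ok = j[:, -1] <= m - 1
        if not ok.any():
            continue
        path_costs = C[np.arange(n)[None, :], j[ok]].sum(axis=1)
        best = min(best, float(path_costs.min()))
    return best


@pytest.fixture
def brute_oracle():
    return brute_force_obe_cost


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_flat_series(
    track: list, n_landmarks: int = len(LANDMARKS), fps: float = 30.0
) -> SkeletonTimeSeries:
    """A series whose every landmark-coordinate equals ``track`` (with
    NaN allowed), convenient for single-track preprocessing checks."""
    t = np.asarray(track, dtype=float)
    data = np.tile(t[:, None, None], (1, n_landmarks, 3))
    return SkeletonTimeSeries(data=data, landmark_names=LANDMARKS[:n_landmarks], fps=fps)


def random_series(
    rng: np.random.Generator, n_frames: int = 20, fps: float = 30.0,
    missing_rate: float = 0.0,
) -> SkeletonTimeSeries:
    data = rng.uniform(0.0, 1.0, size=(n_frames, len(LANDMARKS), 3))
    if missing_rate:
        mask = rng.random(data.shape[:2]) < missing_rate
        mask[0] = False  # keep every track observed somewhere
        mask[-1] = False
        data[mask] = np.nan
    return SkeletonTimeSeries(data=data, fps=fps)


def rendered_clip(
    spec: GestureSpec,
    seed: int = 0,
    noise_sd: float = 0.0,
    hand: str | None = None,
) -> "object":
    """Render a gesture, preprocess it, and extract its stroke clip."""
    series = render_gesture(spec, np.random.default_rng(seed), noise_sd=noise_sd)
    processed, _ = run_pipeline(series)
    fps = spec.fps
    n_lead = max(2, round(spec.lead_s * fps))
    n_stroke = series.n_frames - 2 * n_lead
    seg = GestureSegment(
        dyad_id="d",
        speaker_id="s",
        trial_id="t",
        t_start=n_lead / fps,
        t_end=(n_lead + n_stroke) / fps,
        handedness=hand or spec.hand,
    )
    return extract_clip(processed, seg)


@pytest.fixture
def make_clip():
    return rendered_clip
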