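"""One-off tuning sweep behind the committed perturbation magnitudes.

For each candidate (orientation, position) magnitude pair, generates a
small corpus with single-feature perturbations and reports how far the
perturbed-pair distance distribution separates from the unperturbed one
(difference of means over pooled standard deviation). The constants in
``gesturedtw.synthetic`` were fixed from this sweep once; re-running is
informational only.

Usage: python scripts/tune_magnitudes.py
"""

from __future__ import annotations

import numpy as np

from gesturedtw.compare import pair_distance
from gesturedtw.synthetic import GestureSpec, PairSpec, render_pair


def _clips(pairspec: PairSpec, base: GestureSpec):
    from gesturedtw.preprocess import run_pipeline
    from gesturedtw.segment import extract_clip
    from gesturedtw.timeseries import GestureSegment

    series_a, series_b, _ = render_pair(pairspec)
    clips = []
    for series, hand in ((series_a, base.hand), (series_b, base.hand)):
        processed, _ = run_pipeline(series)
        n_lead = max(2, round(base.lead_s * base.fps))
        n_stroke = series.n_frames - 2 * n_lead
        seg = GestureSegment("d", "s", "t", n_lead / base.fps,
                             (n_lead + n_stroke) / base.fps, hand)
        clips.append(extract_clip(processed, seg))
    return clips


def separation(feature: str, magnitude: float, n: int = 30) -> float:
    rng = np.random.default_rng(99)
    null, alt = [], []
    for k in range(n):
        base = GestureSpec(
            hand="right",
            trajectory_kind=str(rng.choice(["line", "arc", "circle", "zigzag"])),
            direction=float(rng.uniform(0, 6.28)),
            orientation_angle=float(rng.uniform(-2.5, 2.5)),
            center=(float(rng.uniform(0.35, 0.65)), float(rng.uniform(0.25, 0.45))),
        )
        for bucket, perturb in ((null, {}), (alt, {feature: magnitude})):
            ps = PairSpec(base=base, perturb=perturb, noise_sd=0.008, seed=k)
            ca, cb = _clips(ps, base)
            bucket.append(pair_distance(ca, cb).pair_distance)
    null, alt = np.array(null), np.array(alt)
    pooled = np.sqrt((null.var() + alt.var()) / 2)
    return float((alt.mean() - null.mean()) / pooled)


def main() -> None:
    for feature, grid in (
        ("orientation", (0.6, 1.0, 1.3, 1.8)),
        ("position", (0.5, 0.8, 1.0, 1.5)),
        ("movement", (0.5, 1.0, 1.5)),
        ("handshape", (1.0,)),
    ):
        for mag in grid:
            print(f"{feature:12s} magnitude {mag:4.1f}: "
                  f"separation d = {separation(feature, mag):5.2f}")


if __name__ == "__main__":
    main()
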