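# Methods

## Problem setting

Input is tracker output for two speakers: per-frame landmark coordinates
in normalized image units (x, y ∈ [0, 1], y increasing downward, z a
monocular depth heuristic), plus stroke annotations (start/end seconds,
handedness) and, optionally, human per-feature similarity coding of
referentially aligned gesture pairs. The package computes a continuous
dissimilarity per pair and the statistics validating it against the
coding. The tracked skeleton is reduced to what the distance needs:
wrists, five fingertips per hand, shoulders and hips.

## Preprocessing chain

Applied in a fixed order; each step exists to remove a nuisance factor
that would otherwise inflate the distance.

1. **Interpolation.** Occlusion gaps (NaN runs) per landmark-coordinate
   track are filled linearly between flanking observations; leading and
   trailing gaps copy the nearest observation. A track with no
   observation at all raises an error rather than being silently
   invented. Idempotent.
2. **Smoothing.** Gaussian filter per track, σ = 2 frames (default),
   reflect padding, kernel truncated at 4σ (scipy's
   `gaussian_filter1d`). σ = 0 is the identity.
3. **Position normalization.** Every frame is centered on the
   *mid-torso*, defined as the mean of the two shoulders and two hips
   (the tracker provides no explicit torso center). Removes standing
   position exactly (translation invariance to 1e−9 is a tested
   invariant).
4. **Size normalization.** All coordinates are divided by the *torso
   length*: the median across frames of the 3D mid-shoulder→mid-hip
   distance, where mid-shoulder/mid-hip are the shoulder/hip midpoints.
   Dividing (rather than multiplying) by the scale factor is the choice
   that actually removes apparent body size — multiplying a large
   skeleton by its large torso length would amplify, not cancel, size
   differences. The median across frames makes the scale robust to
   single-frame tracking glitches while centering stays per-frame.
   After this step the unit of distance is "torso lengths".
5. **Aspect-ratio adjustment.** x is multiplied by exactly 16/9 so a
   horizontal displacement equals the same physical displacement
   expressed in y units (image coordinates are normalized per axis, so
   a 16:9 video compresses x by that factor). z is never adjusted.
6. **y inversion.** y ← −y so up is positive. Involution.
7. **Relative fingertips.** Each fingertip is replaced by fingertip −
   same-hand wrist, per frame. Wrist channels then carry hand position
   and movement; fingertip channels carry handshape and orientation,
   invariant to any rigid translation of the hand.

By default the distance uses (x, y) only: the aspect correction is
defined for the image plane and monocular z is heuristic. `use_z=True`
includes z (which does participate in the torso-length scale either
way, since that distance is genuinely 3D).

## Alignment

Per keypoint, an open-begin-end DTW with the asymmetric step set
{(1,0), (1,1), (1,2)} in (query, reference) increments: each query
frame is matched exactly once; the reference may stall one frame or be
skipped one frame per step. Local cost is the Euclidean distance over
the active coordinates. The recursion is

    D[i, j] = c[i, j] + min(D[i−1, j], D[i−1, j−1], D[i−1, j−2]),

with free entry anywhere in the first row (open begin) and the result
the minimum over the last row (open end). Open ends make the distance
robust to imprecise stroke boundaries, which is why clips need not be
segmented perfectly. Ties are broken deterministically: smallest exit
index, then diagonal > vertical-repeat > skip during backtracking, so
re-runs are byte-identical.

The cumulative cost is normalized by the **total frame count of both
clips**, D = cost/(n + m), making short and long gesture pairs
comparable. (The conventional normalization for the asymmetric pattern
divides by n alone; the n + m denominator is this pipeline's definition
and only rescales monotonically, so rank-based validation statistics
are unaffected by the choice.)

The per-hand distance is the unweighted mean of the six per-keypoint
distances (wrist + thumb/index/middle/ring/pinky tips). The first clip
of a pair is the query; asymmetric DTW is directional, and a
`symmetrize` option (off by default) averages both directions.

**Hand selection.** Distances are computed for gesturing hands only:
two-handed vs two-handed averages left–left and right–right; one-handed
pairs with the same hand use that hand; one-handed pairs with opposite
hands are compared across hands (A's gesturing hand vs B's); a
one-handed vs two-handed pair takes the minimum over the single hand
against each of the partner's hands (a documented convention — the
choice is not forced by anything upstream, and the adopted branch is
recorded in the output).

**Mirror rule.** For one-handed opposite-hand pairs, B's preprocessed
skeleton is also reflected about the body midline (x ← −x plus
left/right label swap — an involution) and the lower of the
original and flipped distances is adopted, ties favoring the original.
The flag of which won is kept in the output. The rule can only lower
the distance, never raise it (tested invariant).

## Segmentation conventions

Stroke windows are half-open, 0-based: frames [round(t_start·fps),
round(t_end·fps)). Clips shorter than 330 ms — ceil(0.330·fps) frames,
i.e. 10 at 30 FPS, 17 at 50 FPS — are lengthened with *real* frames
from the surrounding recording, the deficit split evenly before/after;
an odd deficit puts the extra frame after the stroke (retraction frames
are kinematically closer to the stroke than preparation), and a
recording boundary spills the remainder to the other side. Padding
never fabricates frames.

## Synthetic corpora

The generator emulates what the tracker emits for a seated speaker, for
testing every stage without recordings:

- static torso (shoulders/hips) with a small sinusoidal sway;
- the gesturing wrist easing from a rest pose through a parametric
  stroke (line, arc, circle, or zigzag; amplitude ~0.08–0.16 image
  units; smoothstep velocity profile) anchored in the upper gesture
  space; fingertips ride on the wrist with one of five handshape
  templates (fist, open, C-shape, point, pinch) rotated by an
  orientation angle;
- two-handed gestures are exact midline reflections across hands;
  mirrored one-handed productions are exact reflections of the rendered
  partner series (x → 1 − x plus label swap);
- Gaussian coordinate noise (default sd 0.008 image units, roughly the
  jitter scale of video pose trackers) and short NaN occlusion runs
  (default rate 0.05) that never delete a whole track;
- stroke durations 0.26–1.5 s at 30 FPS (default), so a realistic share
  of clips falls under the 330 ms minimum and exercises padding.

A pair is a base gesture plus a partner with per-feature perturbations:
handshape = template swap, movement = trajectory-kind change plus a
1.0 rad direction rotation, orientation = ±1.3 rad rotation of the
fingertip frame, position = 0.18 image-unit anchor shift. Unperturbed
features get small natural jitter (0.08 rad orientation, 0.015
position, ±8% amplitude, ±10% duration). The magnitudes are committed
constants chosen once from the separation sweep in
`scripts/tune_magnitudes.py`. Per-feature perturbation flags are
Bernoulli(0.25), calibrating the proportion of "similar" feature
ratings to ≈ 0.75 (the regime the validation targets); the first five
pairs of any corpus are forced to span overlap counts 0–4 so every
similarity level occurs. All randomness flows from one
`numpy.random.default_rng` seed (PCG64), so corpora are reproducible
across platforms.

What the generator does **not** emulate: camera-angle differences
between speakers, perspective distortion of z, correlated (non-i.i.d.)
tracker error, rater disagreement (an optional flip probability exists
but defaults off), and speech context. Passing recovery tests therefore
show that the pipeline recovers graded form similarity under controlled
kinematic perturbations — not that it attains any particular
correlation on real corpora.

## Validation statistics

- **Overlap count**: number of the four features (handshape, movement,
  orientation, position) coded similar, 0–4; handedness is excluded
  because the distance already restricts itself to gesturing hands.
  Ordinal 0–5 ratings are recoded binary with 4–5 = similar.
- **Spearman correlation** between distance and overlap: rho is the
  Pearson correlation of average ranks. Two-sided p-value: t
  approximation (df = n − 2) for n > 20; permutation test otherwise —
  exhaustive over all n! orderings up to n = 8, else 5000 seeded Monte
  Carlo permutations with the add-one correction. Exact-enumeration
  p-values at tiny n are discrete and conservative under tied |rho|
  values; the uniformity calibration test therefore runs in the
  Monte Carlo regime (n = 12), where the null p-value distribution is
  uniform to KS precision.
- **De-meaned slope**: distance regressed on overlap with dyad and item
  intercepts (OLS with dummies — numerically the two-way within
  estimator, exact on unbalanced panels) and HC1 robust standard
  errors. This is a fixed-effects approximation to a varying-intercept
  mixed model and is labeled as such in the report; only the sign and
  rough magnitude are comparable to a mixed-model fit.
- **Incongruence flags**: pairs in the top distance quartile with
  overlap ≥ 3, or bottom quartile with overlap ≤ 1 — the cases worth
  manual inspection (mirrored productions and debatable coding
  decisions typically surface here). The quartile/overlap thresholds
  are a convention of this package.

## Problem sizes and numerical choices

The bundled end-to-end recovery runs on a 200-pair corpus (400
recordings, ~1 s of compute); the alignment oracle checks 1000 random
instances at n, m ≤ 6 and 50 at n ≤ 10, m ≤ 14 against exhaustive
enumeration of all admissible paths (vectorized over the 3^(n−1)
step sequences); null calibration uses 500 replicates. Tolerances:
translation invariance 1e−9, scale invariance 1e−6 (one division),
oracle agreement 1e−6, exact-arithmetic checks 1e−12. Degenerate
inputs: torso length ≤ 1e−6 raises rather than divides; series shorter
than 2 frames are rejected by the aligner (the segmenter's minimum-
duration rule means they cannot arise in the pipeline); constant
vectors make rho and the slope undefined and raise explicitly.

## Known limitations

- The distance is holistic: it cannot attribute similarity to a
  specific feature, and fingertip channels mix handshape with
  orientation by construction.
- Asymmetric DTW is directional; the default takes the first-listed
  speaker as query. `symmetrize` exists but doubles compute.
- The one-vs-two-handed rule (minimum over hands) and the odd-deficit
  padding tie-break are conventions, not forced choices; both are
  logged so analyses can be audited.
- Monocular z is heuristic and excluded from the local cost by
  default; depth-heavy gestures are under-measured.
- Synthetic validation bounds what the tests can claim about real
  video (see above); on real data, validate against a manually coded
  subset before interpreting the distances.
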