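# gesturedtw

Quantify how similar two co-speech gestures *look* — directly from
video-derived keypoint time series.

When two speakers in a dialogue refer to the same object, their gestures
often converge in form: handshape, movement, orientation, and position.
Measuring that convergence by hand is slow (months for a few hundred
gesture pairs) and usually binary. `gesturedtw` provides an automatic,
continuous alternative: it turns MediaPipe-style 3D keypoint tracks into
body-centered kinematics and scores each referentially aligned gesture
pair with a normalized dynamic time warping (DTW) distance, validated
against feature-level human similarity coding.

It is written for gesture and sign-language researchers who already have
(a) per-frame keypoint CSVs from a pose tracker and (b) gesture stroke
annotations (e.g., ELAN exports), and want a per-pair dissimilarity score
plus the statistics to validate it on their own data.

## The measure

For each gesture pair the package:

1. **Preprocesses** each recording: linear interpolation of occlusion
   gaps; Gaussian smoothing (σ = 2 frames); per-frame centering on the
   mid-torso; division by torso length (mid-shoulder→mid-hip distance);
   x-axis stretch by the 16:9 aspect ratio so x and y share units;
   y-axis inversion (up = positive); and re-expression of each fingertip
   relative to the same hand's wrist, so wrists carry position/movement
   and fingertips carry handshape/orientation.
2. **Extracts** each annotated stroke, lengthening clips shorter than
   330 ms (ten frames at 30 FPS) with real surrounding frames.
3. **Aligns** per keypoint with *open-begin-end asymmetric DTW*: every
   query frame is matched exactly once (steps (1,0), (1,1), (1,2) in
   query/reference increments), while the reference's lead-in and
   retraction may be ignored at no cost. The cumulative Euclidean cost
   *d* of the optimal path is normalized per frame,

   D = d / (n + m),

   where n and m are the two clips' frame counts; the per-hand distance
   is the mean over six keypoints (wrist + five fingertips), computed
   for gesturing hands only.
4. **Handles mirrored productions**: for one-handed pairs made with
   opposite hands, the second skeleton is also flipped about the body
   midline and the lower of the two distances is adopted — humans
   perceive mirrored gestures as similar, plain DTW does not.
5. **Validates**: Spearman correlation between distance and the number
   of features coded similar (0–4), a dyad/item de-meaned slope, and
   flagging of incongruent pairs worth qualitative inspection.

A seedable synthetic generator renders full dyadic corpora (parametric
wrist trajectories, handshape templates, occlusion gaps, graded
ground-truth similarity, mirrored pairs), so the whole pipeline is
testable end to end without any recordings.

## Worked example

```sh
gesturedtw simulate --pairs 60 --dyads 6 --items 10 --seed 7 --out demo/corpus
gesturedtw dtw --keypoint-dir demo/corpus --segments demo/corpus/segments.tsv \
    --out demo/distances.csv
gesturedtw validate --distances demo/distances.csv \
    --annotations demo/corpus/annotations.csv --out demo/report.json
```

prints

```
wrote 120 recordings to demo/corpus
wrote 60 pair distances to demo/distances.csv
rho=-0.861 (p=1.1e-18, n=60); wrote demo/report.json
```

`distances.csv` holds one row per gesture pair — the normalized pair
distance, the per-hand and per-keypoint components, which hand-selection
branch was taken, and whether the mirror flip won, e.g.

```
pair_id,pair_distance,mirror_used,n_frames_a,n_frames_b,branch,...
d00_i00,0.200995572783,False,25,25,both-both,...
d01_i00,0.117724993221,False,45,49,one-handed-same,...
```

The validation report says the distance falls as ground-truth feature
overlap rises: Spearman ρ = −0.861 (n = 60 pairs), with a de-meaned
slope of −0.048 ± 0.006 distance units per additional similar feature —
i.e., the measure recovers graded form similarity on this corpus. The
same commands run unchanged on real keypoint/ELAN exports.

The same pipeline is available as a library:

```python
from gesturedtw import generate_corpus, compute_distance_table, validate_corpus

corpus = generate_corpus(n_pairs=60, seed=7)
table = compute_distance_table(corpus.recordings, corpus.segments)
report = validate_corpus(table, corpus.annotations)
```

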