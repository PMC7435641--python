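# Methods

This note documents the models, parameters and design choices behind
`kiwicount`, and what the synthetic-fixture experiments do and do not
demonstrate about real orchard imagery.

## Synthetic canopy scenes

The generator (`kiwicount.synthetic`) emulates what an upward-facing camera
sees under a kiwifruit canopy. A scene is rendered as:

- **Background**: a leaf-green base (RGB ≈ (60, 120, 50)) shaded by
  multi-octave smooth value noise plus per-pixel grain, with elliptical leaf
  blobs and sparse dark *shadow blobs* (RGB ≈ (28, 36, 24)). Shadow blobs
  matter: in grayscale they resemble fruit tips, but their a\* value is
  negative, so background suppression removes them — they are what makes
  the with/without-preprocessing comparison meaningful.
- **Fruits**: brown ellipses (RGB ≈ (139, 115, 85) ± 15) with semi-major
  axis drawn from `fruit_radius_range` (default 14–22 px at the default
  640×480 scene). Each fruit carries one dark circular **tip**
  (RGB ≈ (40, 30, 25) scaled by a per-fruit brightness factor in
  [0.8, 1.6]) of radius `tip_radius_fraction` × fruit radius (default
  0.35), and up to two small **skin blemishes** — dark spots distinctly
  smaller than the tip (radius 0.25–0.55 of the tip radius). Blemishes
  survive background suppression and bound achievable precision: they are
  the irreducible confuser a tip detector faces.
- **Occlusion**: with probability `occlusion_prob` a leaf-colored ellipse is
  drawn over a random part of the fruit. The ground truth records the
  remaining visible fraction of each tip and flags tips less than half
  visible as occluded. Ground-truth counts always include occluded tips —
  the fruit is there whether or not the camera can see its tip.
- **Illumination**: a vertical multiplicative ramp (stronger light from
  below, as with on-vehicle artificial lighting) scaled by
  `illumination_gradient`, and a per-scene defocus blur (σ ∈ [0.4, 1.2])
  for varying canopy depth.

All randomness flows from one integer seed through a counter-based Philox
stream; identical specs render byte-identical scenes. The LAB polarity is a
construction invariant (fruit a\* > 0 > leaf a\*), verified by test.

Frame pairs and sequences are crops of one wide canvas; the true homography
between consecutive frames is a translation by the non-overlapping width,
optionally composed with a small rotation/scale jitter. Frame-level ground
truth is derived from the canvas geometry, so end-to-end counting tests
know the exact number of distinct fruits a panorama should contain.

What the fixtures do **not** model: photo-realistic texture, camera optics,
motion blur, specular highlights, fruit clusters touching each other, or
the full variability of real cultivars. Passing the fixture suite shows the
pipeline's machinery is correct and calibrated under controlled conditions;
it does not certify field accuracy.

## Background suppression

The five-stage chain is: RGB → LAB; Otsu threshold on the 8-bit A channel
(A + 128, clamped); 25×25 majority (median) filter on the binary mask;
dilation by a disc (default radius 12 px, intended to scale with fruit
size); mask application with background zeroed. Choices:

- Foreground is `A8 > threshold` (fruit side of the green–red axis). The
  Otsu tie-break is the lowest maximizing threshold; a constant channel is
  reported as "all background" with a warning rather than an error.
- The median filter runs on the *mask*, not the channel, and is implemented
  as an exact integral-image majority count (an odd window cannot tie);
  `scipy.ndimage.median_filter` is the independent cross-check in the tests.
  Borders reflect without repeating the edge pixel.
- Background is filled with 0 rather than gating detection windows: the
  suppression helps by removing texture, and the detector remains
  independent of the masking logic. Windows straddling the mask boundary
  therefore still reach the detector; the training-window generator
  deliberately samples such windows as negatives.

## The tip detector

- **Features**: five Haar kinds (two-rectangle horizontal/vertical,
  three-rectangle horizontal/vertical, four-rectangle checkerboard) on a
  24×24 base window, enumerated on a stride-3 position grid with sizes from
  6 px up (≈2.7k features by default; `full_feature_pool` enumerates all).
  A feature's value is **mean(shaded) − mean(white)**: normalizing each
  region by its own pixel count makes the value invariant to the integer
  rounding that scaling a feature entails, so stump thresholds learned at
  the base window transfer across detection scales.
- **Boosting**: discrete AdaBoost over decision stumps. Stump training is a
  single sorted scan of cumulative class weights, exactly equivalent to
  exhaustive midpoint-threshold × parity search (property-tested). A round
  with zero weighted error stops training early with the error floored at
  1e−10 (a large but finite vote); a best error ≥ 0.5 aborts with
  diagnostics.
- **Stages and calibration**: stage thresholds start at the natural
  half-vote point, are lowered until at least `d_min` = 99.5% of training
  positives pass, then raised if needed so the stage rejects at least
  `rejection_rate` (default 20%) of its training negatives plus a fixed
  2-percentage-point margin. The margin absorbs quantile-estimation noise so
  the configured minimum also holds on held-out negatives; it was fixed as
  part of the calibration design, not tuned.
- **Training data**: positives are tip-centered crops (side ≈ 4 tip radii,
  jittered in position and scale like imprecise annotations, resized to
  24×24) including partially occluded tips down to 10% visibility;
  negatives mix random background crops, crops centered on dark background
  spots, and crops from masked scenes — half of those centered on the mask
  boundary. Stage-by-stage training adds **scene-level hard-negative
  mining**: after each stage, the partial cascade scans
  background-suppressed training scenes and its actual surviving
  false-positive windows become the next stage's negatives, alongside
  survivors and a dense pre-mined sliding-window pool. This is what drives
  the false-positive rate down at desk scale (training totals: 250
  positives, 1000 negatives per stage, ≤20k pool windows, 5 mining scenes).
- **Detection**: features are scaled rather than the image, so one integral
  image serves the geometric scale sequence (factor 1.25, 3 scales, stride
  2 px at base scale). Candidates surviving all stages are grouped
  greedily: the highest-scoring box absorbs any candidate with IoU > 0.3
  *or* whose center lies inside it (cross-scale duplicates are concentric
  but low-IoU). Inference is deterministic. Classic per-window variance
  normalization is available (`variance_normalize`) but off by default.

### The rejection-rate parameter

`rejection_rate` is interpreted as the minimum fraction of negatives each
stage must reject, enforced by threshold calibration. On these fixtures the
detector separates training classes well, so the natural stage threshold
already rejects 84–100% of negatives and a floor anywhere in 10–50% never
binds: cascades trained across that sweep are identical and the
counting-error curve over the sweep is flat. A genuine trade-off (misses at
high rejection, false alarms at low) would require stage-level class
overlap incompatible with the counting accuracy the rest of the suite
demands; the sweep harness is retained and reports this flatness honestly.
Alternative semantics (threshold placed exactly at the rejection quantile)
were implemented and measured: they produce a monotone error-versus-rate
curve dominated by false positives and much worse absolute accuracy, and
were rejected.

## Stitching

Keypoints are Hessian-determinant blobs (integral-image box-filter
approximation, σ ∈ {2, 3.2, 5, 8}), described by a 64-vector: 4×4
subregions × (Σdx, Σdy, Σ|dx|, Σ|dy|) of Gaussian-weighted gradient samples
taken in a frame rotated to the keypoint's dominant gradient orientation,
L2-normalized. Matching is mutual nearest neighbor under Euclidean distance
with a 0.75 ratio test applied on both sides (keeps matching symmetric).
Homographies come from RANSAC (reprojection threshold 3 px, ≤2000
iterations, 0.99 confidence, seeded) refit on all inliers by normalized
DLT. Compositing is first-image-wins on a canvas sized to the union of
footprints (blending would perturb detector scores), with a configurable
canvas cap guarding runaway homographies. A failed pair splits the sequence
into independent panoramas with a warning — counting then sums over
panoramas, so one bad frame cannot abort a row.

## Counting, yield, evaluation

The count is the number of grouped detections. Yield =
count × representative weight (97.95 g default; `representative_weight()`
computes it from a user-supplied sample of individual fruit weights). APE
is the mean over images of |EC − AC|/AC × 100; a zero actual count is an
error, not a zero. The ablation harness trains one cascade per
(stage-count, rejection-rate) cell — training never sees the preprocessing
switch, which only changes the image handed to the detector — and emits a
tidy table covering both the cascade-number × preprocessing grid and the
rejection sweep.

## Problem sizes and determinism

Default experiment sizes were chosen so the full suite trains and evaluates
on one CPU in minutes: 640×480 scenes with 25 fruits, two-frame panoramas
at 50% overlap, six evaluation scenes per ablation cell, ten panoramas for
the end-to-end benchmark, 100 trials for homography recovery. Every public
operation is a pure function of its inputs and seeds; PNG, CSV and JSON
artifacts reproduce byte-identically under identical configuration, which
the test suite asserts.

## Known limitations

- Synthetic appearance is far simpler than orchard reality; absolute APE
  values here do not transfer to field data.
- The rejection-rate sweep is inert at the fixture's operating point (see
  above).
- Heavily occluded tips (<10% visible) are neither trained on nor reliably
  detected; they stay in the ground-truth count, so the occlusion rate
  lower-bounds the achievable APE.
- The stitcher assumes an approximately planar canopy and ordered frames;
  there is no bundle adjustment or gain compensation.
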