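# Methods

## The detection model

The pipeline assumes a fixed camera watching an automated pipetting station.
During the aspiration phase everything in the scene is static except the
liquid columns rising inside the pipettes, so the absolute difference
between a frame and a fixed *anchor* reference contains (up to noise)
exactly the moved liquid. The algorithm's job is therefore not to model
appearance but to (a) find a stable reference, (b) clean the difference
image, and (c) decide whether what changed looks like `n(p)` healthy liquid
columns.

Anchor detection operationalises "the block has descended and stayed put":
the detected box's top edge must sit at least `min_drop` pixels (default 5%
of the frame height) below the median of its pre-descent values and stay
within `drop_tolerance` (2 px) for `persistence` (10) consecutive frames;
frames with no detection disqualify a window. One fixed crop window — the
anchor box expanded by `expansion_factor` (0.10), slid back inside the frame
rather than truncated so its size is preserved — is used for all later
frames: pixel-aligned differencing requires a fixed window, and the scene is
static during transfer, so per-frame re-cropping would only add jitter.

The difference image is binarised at a fixed grayscale threshold
(`diff_threshold` = 25 on 8-bit channel means). A fixed threshold keeps the
stage deterministic and color-invariant; it assumes the liquid differs from
the empty pipette interior by more than the threshold, which holds for
colored reagents and fails for transparent ones — transparent liquids are
out of scope. Morphological opening uses a square structuring element
(`kernel_size` = 5). Erosion treats out-of-image pixels as foreground and
dilation as background; with a symmetric element this keeps opening
anti-extensive and idempotent (both are tested) while not eroding columns
that touch the crop border, which the bottom of a full column always does.

Contour filtering encodes rig priors in a fixed order: largest-`n(p)` by
area, minimum height/width ratio `r_min` (0.5 — low enough that young, short
columns are not rejected), slot assignment by equal-width partition of the
crop (pipette spacing is fixed, so partitions work and need no tracker),
largest-per-slot, then the vertical-growth check. The growth check compares
a slot's candidate height with the *previous frame's* height for that slot,
with an additive tolerance (`growth_tolerance` = 2 px). Comparing with the
previous frame rather than a running maximum is deliberate: a single
corrupted frame (camera shake) can inflate a height, and a running maximum
would then reject every later correct frame, whereas the per-frame
comparison recovers after one dropped frame. Median-width snapping uses the
median of the surviving widths (even counts: mean of the central pair,
rounded to nearest); each box keeps its x-center, height, area and slot.

## The fill estimate and its bias

The per-slot fill estimate is `sqrt(area_contour / area_pipette)` with
`area_pipette = crop_height × crop_width / n(p)`. Writing `c` for the ratio
of a slot's true column-capacity area to `area_pipette` (about 0.68 under
the default geometry, mostly reflecting the 10% crop expansion and the
inter-pipette spacing), the estimate equals `sqrt(c·f)` for true fill
fraction `f`. This is exact at `f = c`, conservative above it, and biased
*upward* for small `f` — at `f ≈ 0.25` the error peaks near 0.2. The
estimate is therefore trustworthy near the operating points that matter
(empty, and at or above the 50% decision level) and should not be read as a
calibrated level gauge mid-transfer. The simulator's default aspiration is
fast (see below), so its videos only ever expose the estimator near those
operating points, and the test suite's 0.10 accuracy bound is met; on a
station with slow aspiration the mid-transfer readings would be optimistic
even though the end-of-transfer decision would not change.

## Features, classifiers, evaluation

A frame's feature vector concatenates per-slot (x, y, w, h, fill) tuples for
the current frame and the previous `h` frames (default `h` = 13), zero-padded
before the start of the crop sequence; an absent slot contributes an
all-zero tuple, keeping features non-negative for the multinomial model.
Coordinates are raw crop-local pixels; standardisation (train-fold mean and
scale) is applied inside every fit for all models except the multinomial
naive Bayes, which needs the raw non-negative values. Cross-validation is
leave-one-video-out: frames of one video are near-duplicates, and a random
frame-level split would leak them across folds. AUC is the trapezoidal area
of the full ROC polyline (equal to pairwise concordance with ties counted
half); the equal error rate is found by linear interpolation inside the ROC
segment where the false-positive rate crosses the false-negative rate. The
SVC is wrapped in sigmoid calibration (`CalibratedClassifierCV`,
`ensemble=False`) so every model family exposes the same probability
interface.

The rule decision declares a frame normal iff all `n(p)` columns are present
and every fill is at least `fill_threshold` (0.5); it is monotone in the
threshold. The video verdict defaults to the last post-anchor frame, where
fills are maximal and the rule is sharpest; a plateau strategy (first frame
where the median per-frame fill change over `persistence` frames falls below
0.005) is available for streams that continue past the transfer.

## What the simulator emulates

The simulator renders a desk-scale station at 320×240, 30 fps, 120 frames:
a static textured background, an 8-pipette block (16 px wide pipettes, 80 px
columns, 4 px spacing) joined by an effector head bar that starts above the
frame, descends 100 px over 20 frames, and then aspirates to an 80% target.
Aspiration is rapid — the column reaches its level within two frame
intervals (~70 ms), emulating small-volume automated dispensing; this also
keeps the fill estimator inside its accurate regime (above). Clogged tips
admit at most 5% of the target column from the start; bottom-outs stall at
10%. Noise processes are seeded sub-streams per process (toggling one never
changes another's draws): Gaussian sensor noise (σ = 3 in the noisy preset),
whole-frame integer camera shake (probability 0.03, up to 3 px), and a
travelling sinusoidal brightness band just below the tips standing in for
tub ripples (amplitude 20, 10 rows; no quantitative reference exists for
ripple appearance, so its parameters are free). Ground truth — anchor index,
per-frame ROI boxes, per-slot fill fractions (rendered liquid pixel count
over column capacity, exact by construction), anomaly kinds, frame and
video labels — is emitted alongside the frames, and the ground-truth boxes
double as a detection file so the downstream pipeline can be evaluated in
isolation from any detector.

The simulator does **not** emulate: perspective or camera angle, specular
highlights and refraction, transparent liquids, partial occlusion, robot-arm
trajectory faults, autofocus blur, or detector failure modes of a real
object detector. Passing tests therefore demonstrate the pipeline's logic
and its noise handling, not detector robustness on real footage.

The motion-based ROI fallback differences each frame against frame 0 and
boxes the largest changed component. It is a stopgap for scenes where the
moving block enters the frame; when the block is fully visible from frame 0,
the union of vacated and occupied pixels keeps the box's top edge constant
and anchor detection on such a track will correctly report failure. The
detections-file route is the supported path for anchor detection.

## Problem sizes and reproducibility

The shipped study conditions are 20 noise-free videos (10 normal, 10
anomalous) for the rule-based evaluation and 12 noisy videos (6/6) for the
learned evaluation; `scripts/acceptance.py` regenerates both from a seed and
recomputes every reported number end to end. All randomness flows from
`numpy.random.SeedSequence`, so identical configs and seeds reproduce
byte-identical frames, datasets and result tables; the run manifest records
wall-clock stage timings and is the only output file exempt from that
guarantee.

## Known limitations

- The fill estimate's mid-range bias (above) makes it a decision feature,
  not a measurement.
- The fixed difference threshold assumes colored liquid; transparent
  reagents are undetectable by design.
- Slot assignment assumes the detector box spans the full pipette row; a
  half-row detection would scramble slot indices.
- The rule decision inherits the 50% threshold's sensitivity to camera
  distance; it is exposed in the config for per-rig tuning rather than
  auto-calibrated.
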