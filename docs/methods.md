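# Methods

## Problem and pipeline

`skelact` studies viewpoint-agnostic recognition of whole-body unit
actions (the motivating domain is Taekwondo poomsae techniques captured
with an IMU motion-capture suit).  The pipeline is:

1. **3D skeleton clips** — frames × 16 joints × 3 metric coordinates,
   labelled by subject, action class and repetition.
2. **Viewpoint augmentation** — a virtual pinhole camera orbits the
   subject about the vertical axis; each clip is projected to 2D pixel
   skeletons at a configurable set of orbit angles θ
   (p_θ = R_z(θ) p_0, then s^2D = P_θ s^3D with perspective division).
3. **Heatmap volumes** — each 2D clip is cropped to the subject's
   whole-clip bounding box, T frames are sampled uniformly, and each
   frame is rendered as a joint map (sum over joints of
   exp(−D²/σ²) with D the pixel-to-joint distance) or a bone map (same
   kernel on the pixel-to-segment distance).
4. **Classification** — a two-pathway (slow/fast) 3D CNN over the
   T×H×W pseudo-video, trained with SGD and cross-entropy.
5. **Viewpoint experiment** — four classifiers are trained on
   projections at 2, 4, 8 and 36 viewpoints (models A–D) and all are
   evaluated on held-out subjects projected on the full 10° grid,
   measuring how accuracy under unseen viewpoints grows with
   training-viewpoint diversity.

## Heatmap formulation

The kernel is exp(−D²/σ²).  Two conventions in the literature differ
here, so both are switchable in `HeatmapConfig`:

* `denominator`: `sigma2` (default) or `2sigma2` — some related work
  treats σ as a standard deviation with a 2σ² denominator.
* `accumulate`: `sum` (default) or `max` — overlapping Gaussians are
  summed by default; max-accumulation is the convention of some prior
  heatmap pipelines.

Pixel centers sit at integer coordinates and distances are measured in
output-grid pixels after cropping.  Summed joint maps are bounded by the
joint count (16); they are not normalized or clamped.  Joint and bone
maps form separate single-channel volumes and are trained separately —
there is no channel stacking.

## Synthetic motion generator

Real recordings of the motivating study are not distributable, so the
generator emulates the *statistical shape* of such a study rather than
its biomechanics:

* **Study design**: `num_subjects × num_actions × num_repetitions`
  clips; paper-scale is 40 × 16 × 12 = 7680, the desk-scale default is
  6 × 16 × 3 = 288 at 48 frames / 24 Hz (2 s per clip; clip length and
  rate are not fixed by the emulated study and are configurable).
* **Classes**: each action class is a procedural limb program.  The
  4-bit binary code of the class index selects which of the four limbs
  (two arms, two legs) swing — so the 16 default classes differ in
  their *spatial* activation pattern, not only in timing — and
  frequency (0.5 + 0.09·c Hz), amplitude (0.5 + 0.025·c rad), phase and
  swing-plane azimuth (22.5°·c) grow on a deterministic grid.
  All-limbs-idle classes bob vertically instead.  Limbs move by
  forward kinematics (two rigid segments rotated by joint angles), so
  noiseless bone lengths are constant within a clip by construction.
* **Subjects**: one body-scale factor (default uniform in 0.9–1.1) and
  one speed factor (±10%) drawn per subject; repetitions differ by a
  small phase jitter.
* **Noise**: i.i.d. per-frame Gaussian positional noise, default
  σ = 1 cm (the order of IMU-derived joint-position jitter).
* **Reproducibility**: per-clip random streams are keyed by
  (seed, subject, action, repetition), so single clips regenerate
  identically regardless of dataset ordering.

What passing tests on this generator do **not** show: robustness to
real motion-capture artifacts (drift, foot-slide, occlusion-free but
correlated sensor error), to realistic inter-class confusability (real
techniques share sub-movements; these classes are separable by design),
or to pose-estimator noise in externally supplied 2D keypoints.

## Camera model

Perspective pinhole with square pixels, zero skew, principal point at
the image center.  Defaults: 256×256 image, focal 280 px — chosen so a
~2.2 m figure at the default 3 m orbit radius spans about 80% of the
image height — orbit radius 3 m, camera height 1 m, orbit center at the
clip's median pelvis position.  The emulated study names intrinsic and
extrinsic matrices but publishes no values; these defaults are declared,
not inferred.  Points at or behind the camera plane raise an error
rather than being clipped: with sane orbit geometry they indicate
misconfiguration.  Camera-orbit rotation by θ is verified (to 1e−6) to
equal rotating the skeleton by −θ about the orbit axis.

## Classifier and training

Two pathways: the slow path consumes every `slow_stride`-th frame (α=4)
at full width; the fast path consumes all T frames at
`fast_channel_fraction` (β=1/8) of the width.  Time-strided lateral
convolutions (kernel and stride α, channel doubling) fuse fast features
into the slow path before each residual stage; each stage is a stack of
conv–BN–ReLU residual blocks (slow kernels 1×3×3, fast 3×3×3), spatial
stride 2 from the second stage on.  Global spatiotemporal average
pooling of both paths feeds a concatenated linear softmax head.

The stack is implemented directly on numpy (im2col convolutions, manual
backpropagation, float32 arithmetic) and gradient-checked against finite
differences in float64.  Training is plain SGD with momentum 0.9, weight
decay 1e−4, constant learning rate 0.05, and is bit-deterministic given
the seed — there is no nondeterministic kernel to switch off.

**Desk sizing.** The default network is deliberately small —
`base_channels=8`, one residual block per stage, ~6k parameters — and
the experiment path renders 8-frame 24×24 volumes.  Measured on one CPU
core this costs ~1.5 ms per sample forward+backward, which lets the full
four-model experiment (≈9.6k training volumes, 3.5k test volumes) run in
about two minutes.  Every knob scales upward; the emulated study's
network dimensions are unpublished, and its reported parameter count is
not a target.

**Equal-compute budgets.** `TrainConfig.max_updates` (default 500 for
the experiment paths) caps minibatch updates in addition to the epoch
cap, so models A–D — whose training sets differ 18× in size — receive
the same optimizer work.  Without it, epoch-based training would
confound viewpoint diversity with total gradient steps.

## Evaluation

Per-class precision/recall/F1 via one-vs-rest reduction of the confusion
matrix; aggregates are macro averages (unweighted per-class means) and
accuracy is micro (trace/total).  Macro was chosen because the emulated
study's printed per-model aggregate F1 is consistent with per-class
averaging rather than with the harmonic mean of its printed aggregates.
Undefined ratios (empty denominator) score 0 and the class index is
recorded in the report's `undefined_*_classes` fields.

Splits are subject-disjoint everywhere: the holdout split and each of
the k cross-validation folds assign whole subjects, never clips — the
defensible unit for subject-generalization claims.  With the 6-subject
desk study and 5 folds, fold sizes are 2,1,1,1,1 subjects.

## Numerical choices and degenerate inputs

* Point-to-segment distance: projection parameter clamped to [0, 1];
  coincident endpoints fall back to point distance.
* Crop: padded box mapped by uniform scale + centering (letterboxing);
  a zero-area box (all keypoints at one point) is an error; a box
  degenerate in one axis letterboxes along the other.
* Uniform sampling: T_out equal contiguous bins; deterministic bin
  centers for evaluation, seeded random-within-bin for training
  augmentation; indices repeat when T_in < T_out.
* Ties in argmax predictions resolve to the lowest class index.
* Angle grids require the spacing to divide 360 exactly.

## Known limitations

* The generator's classes are separable by construction; absolute
  accuracies on it say nothing about accuracies on real recordings —
  only the *relative* viewpoint-diversity trend is meaningful, and that
  trend (two-view model A well below the 8- and 36-view models C/D
  under unseen viewpoints) is what the experiment reproduces.
* The numpy network is single-threaded-friendly but not suited to
  large-scale training; there is no GPU path.
* Confidence values on imported 2D keypoints are carried but not used
  to weight Gaussians (projected skeletons have no confidences).
* No occlusion, lens distortion, or multi-person reasoning.
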