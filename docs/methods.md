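# Methods

## The measurement

Cervical sagittal alignment is quantified by the C2–C7 Cobb angle on a
lateral radiograph.  Four anatomic landmarks define it: the anterior and
posterior endpoints of the C2 and C7 inferior endplates.  With image
coordinates x rightward and y downward (the raster/labelme convention),
the slope of an endplate is

    slope = atan2(y_posterior − y_anterior, x_posterior − x_anterior)

in degrees, clockwise positive, wrapped into (−180°, 180°] with ties at
the branch cut resolved to +180°.  The C2–C7 angle is

    C2–C7 = C7 slope − C2 slope

so lordosis (the normal posteriorly concave neck curve) is negative and
kyphosis positive.  The canonical input orientation is
patient-facing-left (anterior corner at smaller x); facing-right images
are mirrored first (`--facing right` on the CLI, `LandmarkSet.mirrored`
in the API).  Mirroring negates the Cobb angle and reflects each slope
about the vertical, which is why a single canonical frame is enforced
rather than a per-image guess.

Range of motion is defined as flexional ROM = flexion − neutral and
extensional ROM = neutral − extension; with the kyphosis-positive sign
convention both are positive for normal motion.  No consensus formula
exists in the measurement literature for the decomposition; this is the
one consistent with the sign convention and it is stated here explicitly
because reported ROM values depend on it.

## Landmark localization model

Landmarks are localized by heatmap regression: the network maps a
grayscale radiograph to four likelihood maps in [0, 1] (channel order
C2A, C2P, C7A, C7P); each landmark is the argmax of its map.  The peak
value of each map is that landmark's confidence, and the minimum of the
four peaks is the radiograph's confidence score — a single number in
[0, 1] that can gate which automatic measurements are accepted.

Training targets are isotropic Gaussians, peak-normalized to 1, with
σ = 8 px at a 128-px heatmap grid and scaled proportionally for other
grid sizes.  Two deliberate refinements:

* **Continuous target centers.**  Targets are centered on the exact
  (sub-pixel) landmark position rather than the nearest grid cell, so
  decoding accuracy is not floored by grid quantization.  The
  stand-alone `encode_heatmaps` utility snaps to the nearest cell (peak
  exactly 1.0), which gives the exact encode→decode round-trip identity
  used to validate the codec; the trainer uses the continuous variant.
* **Log-parabolic sub-pixel decoding** (optional flag, on in the
  estimator, off in the plain `decode_landmarks` default): a 1D parabola
  is fitted to the log-intensities around the argmax along each axis,
  which is exact for Gaussian-shaped peaks.  Offsets are clamped to half
  a cell and the refinement degrades gracefully to the integer argmax at
  borders or on non-positive neighbourhoods.

Predicted maps are clipped to [0, 1] before peak extraction so the
confidence contract holds even if a network head misbehaves; the
bundled networks end in a sigmoid, which makes clipping a no-op.  The
output head's bias is initialized to −3 so the initial maps are close
to the mostly-background targets; this removes a plateau at the start
of training.

Two network variants share one NumPy engine (im2col convolutions,
instance normalization, ReLU/sigmoid, 2×2 max-pool, nearest
upsampling, Adam, manual backprop; single-threaded, exactly
reproducible given a seed):

* `desk_scale` — a small U-Net-style network: a strided 3×3 stem to
  half resolution, a second strided conv to quarter resolution, two
  context convs at quarter resolution (the second with dilation 2),
  nearest upsampling back to half resolution where the context features
  are concatenated with the stem features, and a sigmoid head (default
  24 base channels).  Each conv is followed by instance normalization
  and ReLU; the norm layers are what make from-scratch convergence fast
  enough for CPU budgets, and the high-resolution skip path is what
  gives the head crisp edges to localize against.  Input 128×128,
  heatmap 64×64.  Besides the intensity plane, the input carries two
  normalized coordinate planes (CoordConv-style): the two endplate
  corners of C2 and of C7 are locally similar, and at the receptive
  fields affordable here the network needs global position to tell
  them apart reliably.
* `paper_scale` — the same engine, wider and deeper, with an atrous
  (dilation 2 and 4) context stack; input 256×256.  Its configuration
  snapshot records the full-scale clinical design it parallels
  (DeepLabV3-style decoding over an EfficientNet-B4 backbone).  It is
  buildable and trainable but not sized for CPU-budget experiments, and
  no pretrained weights ship with the package.

### Training protocol

Adam with initial learning rate 0.001, RMSE over all heatmap pixels and
channels as the loss, batch size 8.  Early stopping monitors a
patient-level validation split (10 % of training patients, seeded):
training stops once validation loss has not improved for `patience`
epochs and the best epoch's weights are restored, so the returned model
never has a validation loss above the recorded minimum.  The learning
rate is held at its initial value: step and plateau decay schedules
were tried during development and slowed convergence at these epoch
budgets.  One master seed
fans out to independent init/split/shuffle streams; two runs with the
same seed produce identical losses.

Images are preprocessed by resizing the longest side to the network
input size, padding to square, and scaling intensities to [0, 1];
landmark coordinates follow the same affine and predictions are mapped
back through its inverse.  Angles are scale-invariant, so the resize
does not bias the measurement.

### Cross-validation and learning curves

Validation is patient-level fivefold: patients (never single
radiographs) are partitioned uniformly at random into five balanced
folds, each fold is measured by a model trained on the other four, and
the pooled records cover every radiograph exactly once.  The
learning-curve utility trains on nested random patient subsets of
increasing image count against a fixed, patient-disjoint test manifest.

## Evaluation toolkit

* **Error summaries**: mean, sample SD (n−1), median (midpoint of the
  central order statistics), max of absolute errors.  SD of a single
  value is NaN, not 0.
* **Exclusion curves**: at threshold t, records with confidence ≥ t are
  retained; the excluded fraction, MAE and maximum error over retained
  records are reported.  Retained sets are nested, so the maximum error
  is non-increasing and the excluded fraction non-decreasing — this
  holds for any record set and is property-tested.
* **Posture confusion metrics**: per-class recall, precision and F from
  a 3×3 confusion matrix (rows true, columns predicted, order
  flexion/neutral/extension), overall accuracy, macro means.  Zero
  rows/columns yield NaN entries that are excluded from macro means.
* **Measurer comparison**: all measurers score the same radiographs, so
  a two-sided *paired* t-test compares the reference measurer's
  absolute errors against each other measurer, with Bonferroni
  adjustment by the number of comparisons.  Zero-variance differences
  return p = 1.0 with a warning rather than failing.
* **Outlier flagging**: per posture and quantity (C2 slope, C7 slope,
  C2–C7 angle), the 2.5th and 97.5th percentiles of reference
  measurements (linear interpolation between order statistics) form
  plausibility bounds; a measured value strictly outside its bounds is
  flagged and human confirmation recommended.  Values exactly on a
  bound are inside.  `OutlierBounds.from_cohort()` provides bounds from
  the normative clinical cohort statistics.
* **Posture classifier**: a Gaussian class-conditional model on
  (C2 slope, C7 slope) with empirical priors; ties break toward the
  larger prior, then the fixed posture order; singular covariances fall
  back to their diagonal with a warning.

Reported tables round half away from zero, applied only at reporting
time; all stored values are full precision.

## The phantom generator

The generator emulates the *structure* of a clinical flexion/neutral/
extension cohort so the pipeline can be exercised without patient data:

* Per-posture C2–C7 angles are drawn from truncated normals whose mean,
  SD, minimum and maximum default to the normative cohort statistics
  (flexion 14.3° ± 15.6°, neutral −9.4° ± 15.8°, extension
  −25.1° ± 18.6°).  The C2 slope is drawn from the posture's cohort
  marginal (truncated at ±2 SD for renderability) and the C7 slope is
  set to C2 slope + angle — the simplest joint distribution consistent
  with the angle identity and the cohort marginals.
* Six vertebral bodies are laid out along a curve whose C2 and C7
  inferior endplate orientations realize the sampled angle exactly;
  interior vertebrae interpolate the total rotation with per-patient
  jittered segment shares.  Ground-truth landmarks are the analytic
  endplate corners, so the emitted annotation reproduces the sampled
  angle to floating-point accuracy (verified to 0.1° in tests over
  hundreds of patients).
* Difficulty artifacts mirror clinically observed failure modes:
  osteophyte spurs drawn beyond a corner (the ground truth stays on the
  original corner — the standard marking rule), fused vertebrae,
  posterior instrumentation strokes, and a bright shoulder band across
  the C7 region.  Artifact probabilities default to a degenerative
  referral population (osteophytes 0.40, instrumentation 0.17 — the
  cohort's surgical fraction —, fusion 0.08, shoulder occlusion 0.30
  per image).  Artifacts use a random stream separate from geometry, so
  they are decorative by construction: toggling them never moves the
  ground truth for a fixed seed.
* Rendering is schematic: soft-edged bright quadrilaterals, a
  low-frequency bias field, Gaussian noise, 8-bit quantization.  There
  is no projection physics, no soft tissue, no true occlusion of the
  landmark corners, and no pediatric or congenitally malformed anatomy.

Each patient derives its random stream from (master seed, patient id),
so datasets are bit-reproducible and extensible patient by patient.

**What phantom results do and do not show.**  Phantom experiments
validate geometry, data plumbing, training mechanics and the monotone
behaviour of confidence gating.  Phantom error magnitudes are artifact
properties: the phantoms lack the hard content of clinical radiographs
(true C7 obscuration, deformity, anatomical ambiguity), so clinical
error statistics — cohort MAE, surgeon-comparison p-values,
exclusion-curve operating points at specific thresholds, error vs
training-set-size values at clinical scale — are *not* reproduced at
desk scale and are not claimed by any test here.

## Problem sizes used by the bundled experiments

The desk-scale end-to-end experiment trains on 150 phantom patients
(450 images at 128×128), evaluates on 50 held-out patients, and uses a
22-epoch budget with patience 6 (validation loss is near its plateau
there); the acceptance run reports a single seed, the test suite the
median of three seeds.  The learning-curve
check runs at 64 px with small patient counts.  These sizes are chosen
so the whole pipeline — generation, training, evaluation — completes in
minutes on a single CPU core while leaving clear daylight between a
trained and an untrained model.

## Known limitations

* The NumPy engine has no GPU path; `paper_scale` is present for
  architectural fidelity, not for practical training at clinical scale.
* Heatmap argmax decoding is single-peak; a bimodal map (e.g. C6/C7
  confusion) decodes to the taller mode with no multi-hypothesis logic
  — mirrored clinically by large maximum errors in rare cases.
* The posture classifier's achievable accuracy on phantom draws is
  bounded (~0.8) by the overlap of the neutral and extension marginal
  distributions under the marginals-only joint; clinical joint
  structure is likely more separable.
* DICOM ingestion applies deterministic min–max windowing by default;
  VOI LUT windowing is opt-in.
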