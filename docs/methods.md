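# Methods

`pawprint` classifies short open-field behavior clips of infant rodents
into two treatment groups with a recurrent network, explains the
classification frame-by-frame with layer-wise relevance propagation
(LRP), and quantifies the movement features the explanation points at
(initial posture, periodic stereotypy, locomotion) with classical
kinematic scoring and pose-track statistics.  This note records the
models, the defaults and why, the synthetic data the pipeline is tested
on, and the numerical choices that were genuinely open.

## Classification pipeline

**Clips.** Raw recordings (default 30 frames/s) are subsampled to every
10th frame and windowed to 150 frames (50 s) starting at a per-trial
offset that skips the handler releasing the animal.  Frames are
converted to luminance, optionally center-cropped to the arena bounding
box, and resized to 400 x 350 (bilinear; block-average "area"
interpolation is available when the downscale factor is integral).
Cropping before resizing preserves the arena's aspect ratio; the
alternative (anisotropic resize of the full frame) is supported but not
default.

**Frame features.** Each frame is reduced to a fixed-length feature
vector.  The default backend tiles the frame into a 10 x 10 grid of
patches and emits each patch's mean intensity and mean gradient
magnitude (200 features): deterministic, weight-free, and sufficient
for the coarse body-configuration and body-position information the
classifier needs.  A pretrained 2,048-feature convolutional backend
(the global-average-pool layer of a standard image-classification
network) is declared with the same contract for use where a deep
learning framework and its weights are available; it is not required by
any test.  Swapping backends changes only the feature count.

**Sequence classifier.** A single LSTM layer (default 256 units) reads
the feature columns in frame order; its final hidden state passes
through dropout (rate 0.2) and a 2-unit softmax layer.  The probability
of the control class is the "output-neuron activity" in [0, 1];
`classify` thresholds it at 0.5, assigning control at the boundary (a
measure-zero tie rule).  The LSTM, backpropagation through time, Adam,
and dropout are implemented directly on numpy arrays, so training,
prediction, input gradients and relevance propagation share one exactly
reproducible float32 computation: a fixed seed reproduces weights
bit-for-bit.

Training defaults: Adam at learning rate 1e-3, batch size 100,
30 epochs, cross-entropy loss, Glorot input weights, orthogonal
recurrent blocks, forget-gate bias 1.  Features are z-scored per
feature using training-fold statistics only (never the test fold), with
a variance floor: a feature whose training sd falls below 0.1x the
90th-percentile sd is scaled by that floor instead of its own sd.
Without the floor, patch features of empty background — whose variance
is pure pixel noise, two orders of magnitude below animal-bearing
patches — are amplified into unit-variance noise channels that dominate
the input and invite overfitting.  On the small cohorts used here
(tens of trials per fold) the default batch size degenerates to
full-batch training, which converges slowly in steps; the experiments
in the test suite therefore use smaller batches (8–16) and a mildly
higher learning rate (3e-3), noted per experiment.  Gradients are
clipped elementwise at ±5.

An optional training-time augmentation (`time_crop_frames`) trains each
batch on a random contiguous window of the clip; prediction always uses
the full clip.  The cue of interest — *when movements recur* — is
invariant to time translation, while memorizing individual trials is
anchored to absolute frame indices, so random crops push the model
toward the generalizable temporal rule.  On the planted-stereotypy
experiments this is the difference between chance-adjacent and ~0.9
held-out accuracy.  Model width matters little once the cue is learned
(the experiments use 128 units; 256 and 512 land within a few points),
matching the robustness expectation for this architecture.

**Cross-validation.** Grouped k-fold (default k = 5) with all trials of
one animal (optionally one litter) in the same fold, so a predicted
animal is never in its own training set; every trial is predicted
exactly once, and a leakage assertion re-checks the partition on every
result.  Accuracy is pooled over folds; per-group mean ± SEM of the
output activity is reported alongside.

## Knowledge extraction

**LRP.** The control-class *pre-softmax* score is decomposed into
additive per-input relevances.  Dense layers use the epsilon rule
(stabilizer default 1e-6).  Through the LSTM the established recurrent
convention is used: at each multiplicative interaction all relevance
follows the signal path — the hidden state routes to the cell state,
the cell state splits between the forget path (to the previous cell
state) and the input path (to the candidate input) in proportion to
their contributions — and none is assigned to gate activations.  The
linear maps inside the candidate branch then use the epsilon rule to
split relevance between the current input column and the previous
hidden state.  Conservation holds up to the epsilon leak plus the share
absorbed by biases and the initial state; the toy-model tests verify it
to 1e-3 relative on bias-free dense nets, where it is exact.

**Gradient x input** of the same pre-softmax score is provided as the
fallback explanation method; on purely linear models it coincides with
LRP exactly.  On recurrent models the two methods agree well for
moderately fit models and drift apart as the model saturates: a
saturated softmax flattens occlusion and gradient signals while LRP
keeps redistributing the (large) logit.  Agreement and
occlusion-oracle checks in the test suite therefore use moderately
trained models; this is a property of attribution methods, not of this
implementation.

**Frame importance** collapses the relevance matrix column-wise; the
default rule is the sum of absolute relevance per frame (signed and
positive-part sums are provided — the choice of magnitude aggregation
is documented in each output).  Group mean ± SEM curves and their
difference are emitted together.  Importance curves from recurrent
models ride on a slow drift (evidence closer to the decision retains
more relevance), so *peak* frames are identified after subtracting a
running-median baseline (window 9 frames — above the 1-frame peak
width, below the drift scale), and the spectral analysis of an
importance curve is applied to the same baseline-corrected signal so
that drift power does not inflate the significance reference.  Because
single trained networks vary in how sharply their relevance resolves
individual frames, importance curves in the planted-signal experiments
are additionally averaged over a few random weight initializations
(each run starts from fresh random weights) before peak and spectral
analysis.

**Pixel maps.** For the patch backend each feature maps exactly to its
patch, so feature relevance is spread uniformly over the patch pixels —
an exact correspondence used to check that explanation mass lies on the
animal rather than on background.

## Stereotypy detection

The dominant period of an importance curve (or any per-frame signal)
comes from the one-sided periodogram of the mean- and linear-detrended
signal, searched between a minimum period of 2 frames and a maximum of
a third of the signal length (at least three repetitions must support a
period call; slower components are indistinguishable from trend).  The
spectral argmax is refined by the autocorrelation peak near it, with
parabolic sub-frame interpolation; because the argmax of a
non-sinusoidal cycle can land on the second or third harmonic, doubled
and tripled candidate periods compete by autocorrelation height
(standard octave correction).  A peak is significant when its power
exceeds 12x the median power of the searched band — calibrated so white
noise is flagged periodic in under 5% of runs (the Monte-Carlo null is
part of the test suite); the period in seconds is period_frames divided
by the effective frame rate, so an 11-frame period at 3 frames/s is
3.7 s.  Period-aligned segmentation cuts a clip or track into
floor(T/P) whole segments, dropping the remainder, and reports segment
start indices for montage rendering.

## Kinematic scoring

The open field is a 20 cm x 30 cm box ruled into 2 cm x 2 cm squares
(10 columns x 15 rows = 150 squares).  Cells are half-open with the far
arena boundary belonging to the last cell.  The four start squares are
the unique centered 2 x 2 block; the inner region is the central
6 x 11 block (everything at least two squares from each wall) and the
outer region the two-deep perimeter ring (84 squares).  A square-entry
event occurs whenever a front paw's square differs from its square at
the previous scored frame; frames where a paw's keypoint likelihood
falls below 0.6 (configurable) are skipped for that paw with the last
known square carried over.  `total` counts all events of both paws;
`novel` counts distinct entered squares with the start block excluded
(maximum 146) — entries *into* start squares still count toward
`total`, since every square-to-square transition does.  Inner/outer
splits attribute an event to the region of the square being entered.
The scorer is validated cell-by-cell against a brute-force
rectangle-membership recount on random walks.

## Pose metrics

*Initial limb spread* is the mean of the four fore x hind limb
Euclidean distances at the first frame (ipsilateral-only mode is
provided; the four-pair mean is the default and is recorded in output
metadata).  *Nose return distance* is the distance between the nose at
the 1st and 11th analysis frames (any pair may be requested, e.g. 3rd
and 14th); small values mean a movement cycle returned the animal to
its starting pose.  Frame indices are 1-based at this interface and
nowhere else.  Trajectory fans translate each nose path so frame 1 is
the origin.  Group comparisons offer Welch's t, Mann-Whitney U and
two-sample Kolmogorov-Smirnov, all two-sided; identical zero-variance
groups return p = 1 with a warning rather than an error.

## Expert-measures baseline

Five standard families (decision tree, random forest, logistic
regression, k-nearest neighbors, support-vector machine) with library
defaults and a fixed seed, fit on the six measures z-scored within
training folds, under the same grouped folds as the network.  PCA on
the standardized measures reports scores, loadings and explained
variance; with labels it also reports a class-overlap scalar (the
within-class share of total PC-score variance: ~1 means the classes
overlap fully).  Plain centered PCA (no standardization) is available
and is what makes the variance spectrum rotation-invariant.

## Synthetic open-field cohorts

The generator produces two-group cohorts of rendered clips plus exactly
matching keypoint tracks; every planted effect is recoverable by the
corresponding pipeline stage, which is what the tests and the
acceptance experiments exercise.

**Body and rendering.** A white ellipse with five bright dots (nose and
four limbs) and a tail-base/body-center track on black background, at
400 x 350 by default; Gaussian pixel noise (sd 2 on the 0–255 scale)
and keypoint jitter (sd 0.5 px) are configurable.  The limb geometry is
solved in closed form so the frame-1 mean fore x hind distance equals
the sampled limb-spread value exactly.  The rendered blob centroid
recovers the body-center track to within 1 px.

**Movement.** Infant warm-up movement is modeled as in-place wander: the
body position and heading follow mean-reverting (AR(1)) processes
around the placement point and orientation, with per-frame displacement
sd calibrated so a paw's expected grid-square crossing rate matches the
group's `locomotion_rate` (entries/s).  The persistence 0.775 is chosen
so the stationary spread matches the peak excursion of an 11-frame
movement cycle — planted and unplanted animals then occupy comparably
sized patches of the arena and differ in movement *timing*, not range.
The nose makes lateral oscillations about the body axis with a drifting
phase, so an unplanted animal's lateral movements are rhythmic but not
strictly periodic.

**Stereotypy.** A planted period P turns each consecutive block of P
frames into a closed movement cycle, governed by two dials.
`return_fidelity` (r) controls how reliably the pose *returns*: an undo
of fraction r of the cycle's net displacement, heading drift and
oscillation-phase drift is spread over the first P−1 steps, with a
near-pause step at the boundary — the body is carried back toward its
cycle-start pose *by the cycle's last frame*, a return movement rather
than a teleport.  `pattern_fidelity` controls how exactly the
in-between movement *repeats*: cycle increments are a correlation
blend of a fixed base cycle and fresh randomness (sqrt weights keep
the marginal step variance equal to an unplanted animal's).  The
treated defaults (return 0.9, pattern 0.5) plant a stereotypy whose
defining temporal event is the recurring pose at the period multiples,
with loosely repeating movement in between; with both dials at 1 the
whole track is P-periodic to machine precision.  A rate correction
compensates the step-magnitude shrinkage from cycle closing so
periodic animals still deliver their nominal locomotion rate.  The
planted lateral swing completes one full cycle per period.

**Group parameter defaults** (the package's standard study conditions):
the control-like group starts moving immediately
(`start_latency_frames` 0), at 0.95 squares/s (57 entries per 60 s),
with frame-1 limb spread 87.57 ± 10 px; the treated-like group lingers
10 effective frames before moving, moves at 0.70 squares/s (42 entries
per 60 s), has limb spread 96.2 ± 10 px, and carries an 11-frame
stereotypy at fidelity 0.9.  The spread means and entry rates are the
planted group contrasts the pose and kinematic stages are asked to
recover; the within-group sd of 10 px makes the posture contrast a
~0.86 sd effect, detectable at n = 50/group — a deliberately
test-sized effect.  `temporal_contrast_params()` builds the stricter
cohort in which the groups differ *only* in the planted period: per-
trial summary measures then carry almost no signal and only a sequence
model separates the groups, which is the pipeline's central contrast.
(A periodic path still revisits slightly fewer unique squares than a
free wander — complete summary-measure blindness is unattainable — so
the baseline lands modestly above chance there while the sequence
classifier is expected well above it.)

**Determinism.** Per-trial seeds derive from (master seed, group index,
trial index), so a cohort is bit-reproducible and enlarging it never
reshuffles existing trials.

**What the generator does not emulate:** photorealistic appearance,
pose articulation beyond a rigid body frame, gait, wall-following
(thigmotaxis), inter-animal variability in body size, or tracking
failures other than uniform keypoint jitter.  Passing tests show the
pipeline recovers planted effects of realistic size under controlled
conditions; they do not show that real videos carry those effects.

## Problem sizes used in tests and experiments

The planted-signal pipeline experiment uses 40 + 40 trials of 150
frames at 400 x 350 with the patch backend — large enough for grouped
5-fold training to generalize, small enough to run on a single CPU in
minutes.  Feature-level cohorts (planted bumps on Gaussian noise) stand
in for the video stage wherever a test exercises only the classifier or
the explanation machinery.  Null-calibration checks use label
permutations against exact binomial chance bands.

## Where frame-locked importance peaks come from

A subtlety worth recording: per-frame importance peaks every P frames
require the model's evidence to be anchored to *absolute* frame
indices.  When the only group difference is a recurrence rule
("the pose at t matches the pose at t − P"), the evidence is
time-translation-invariant, and measured leave-one-frame-out occlusion
profiles of models trained on such cohorts are accordingly smooth
accumulation curves with no P-periodic structure — no attribution
method can honestly display peaks the evidence does not have.  Peaked
importance arises when the class is defined by what happens *at*
specific frames (e.g. bumps at frames 1, 12, 23, ...), which is how the
planted-signal importance experiments are constructed; the video-cohort
experiment instead validates classification accuracy, where the
translation-invariant cue is exactly what the crop-augmented sequence
model learns.

## Known limitations

* The pretrained convolutional backend is declared but cannot run
  without a deep-learning framework and downloaded weights; pixel-level
  relevance is exact for the patch backend only.
* Epsilon-LRP magnitudes through a long LSTM grow toward early frames
  (signed splits with cancellation); conclusions are drawn from peak
  structure and spectra of importance curves, not from absolute
  relevance magnitudes.
* Video containers require an imageio plugin; PNG-sequence directories
  are the native interchange format.
* The grid scorer's treatment of start-square re-entries (counted in
  `total`, excluded from `novel`) is one defensible reading of the
  scoring procedure; it is recorded in output metadata.
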