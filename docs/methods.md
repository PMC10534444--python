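# Methods

`fallhic` assesses head-impact severity for a small child falling at home,
from nothing but a surveillance camera's 2D skeleton track.  The pipeline
has two phases.  Phase I restores a usable kinematic signal from imperfect
pose estimation: occlusion gaps in the 25-joint 2D track are imputed by a
gated recurrent sequence model, and each repaired frame is lifted to 3D by
a residual multilayer network.  Phase II turns kinematics into a clinical
quantity: the head-center trajectory is differentiated to a resultant
acceleration history, scored with the windowed Head Injury Criterion
(HIC-15), and mapped onto a four-level severity scale; a conventional
classifier (random forest or SVM) over trace-derived features provides a
robust alternative to direct thresholding.

Because real fall footage of children cannot be redistributed, the package
ships a fall simulator with analytically known head kinematics.  All
benchmarks in `tests/` and `scripts/acceptance.py` run against it.

## The severity scale

For a resultant head acceleration `a(t)` in units of g,

    HIC = max over (t1, t2) of  (t2 - t1) * [ (1/(t2-t1)) * ∫ a(t) dt ]^2.5

with `t2 - t1` capped at 15 ms (36 ms is available via `window_cap`).  The
integral is trapezoidal and the search is exhaustive over all sample-aligned
windows; a plain double-loop reference (`compute_hic_exhaustive`) is kept as
the oracle the vectorized search must match exactly.  Sub-sample window
endpoints are not searched — the error is bounded by one sample period, and
callers who need finer placement can resample the trace first.

Severity: HIC < 250 no injury; 250–700 minor (concussion range); 700–1000
moderate (~5% serious-injury probability); ≥ 1000 heavy (~33% skull-fracture
probability).  Scores exactly on a boundary go to the *higher* class: the
mapping is then right-continuous and errs toward alerting.

## Keypoint repair

The imputer is a bidirectional LSTM over window-normalized coordinates
(neck-centered, torso-scaled — pixel-scale inputs saturate the sigmoid
gates).  Missing joints enter the recurrence as zeros gated by a parallel
mask channel; the input also carries the per-joint linear interpolant of
the observed samples.  A linear output head combines the forward and
backward hidden states of each frame into a *residual* on that interpolant,
so the untrained model already realizes interpolation and training only has
to learn the structure interpolation misses: the velocity kink at impact,
and cross-joint rigid-body constraints that localize a joint from its
observed neighbors.

Two hard contracts, enforced structurally rather than learned:

* observed coordinates pass through bit-identically;
* a frame's prediction depends only on frames within the memory horizon
  (≤ 100): sequences are processed in overlapping windows and each frame is
  predicted by the window it is most central in.

Training minimizes mean squared error on masked coordinates only, over
random window crops (window 64 frames, four crops per sequence per epoch).
The loss is restricted to the positions inference would actually consume
from a window at that location (the central half; a boundary half when the
crop touches a sequence edge) — without this, window-edge extrapolation
cases that are never used dominate the gradient.  The optimizer is Adam
(2e-3, exponential decay 0.97/epoch) with weight decay 5e-4 and global
gradient clipping; plain momentum SGD (0.937) is available as a config
option but converges considerably more slowly on this recurrence.  The
recorded loss history is evaluated after each epoch on a fixed probe crop
set, so it reflects model progress rather than crop-sampling noise.
Sequence-boundary gaps are imputed from one-sided context and flagged
`extrapolated`.

## 2D-to-3D lifting

A residual MLP maps the 50 numbers of a frame (neck-relative 2D in meters
at the subject depth) to 75 (neck-relative 3D in meters): a linear
embedding to width 1024, two residual blocks of two
[linear → batch standardization → ReLU → dropout] layers, and a linear
output head.  Every linear layer's per-unit incoming weight vector is
projected to norm ≤ 1 after each optimizer step (max-norm, jointly with
batch normalization).  Training uses Adam at 1e-3 with exponential decay
0.96 per 1000 steps and batch size 32, minimizing mean squared 3D error.

A single view cannot fix absolute depth.  The network output is
root-relative; `lift_sequence` anchors it in the lab frame from the neck's
pixel position via the sequence's meters-per-pixel scale, with depth fixed
at the nominal subject plane.  Vertical motion is therefore recovered up to
a constant offset — sufficient for differentiation.

## Head center and acceleration

The head center is the mean of the head-region joints (nose, eyes, ears),
optionally offset toward the cranial centroid (default offset 0; the
surface keypoints already straddle the head).  Frames whose source 2D
observed fewer than two head joints are flagged low-confidence; a fully
concealed head simply uses the lifted estimate, which the body joints
constrain.

Acceleration is obtained per axis by local quadratic least-squares
(Savitzky–Golay) smoothing followed by central second differences — exact
for quadratics, hence exact during free fall.  The smoothing window covers
a fixed *time* span (~30 ms) rather than a fixed frame count: pose jitter
is amplified by fps² under double differencing, so the window must scale
with the frame rate; 30 ms balances jitter suppression against attenuating
O(10 ms) impact pulses.  The resultant magnitude (including gravity; a
`subtract_gravity` flag is provided) divided by 9.81 m/s² gives the trace
in g.

## The fall simulator

A fall is: quiescent pre-roll at `drop_height` above impact level; free
fall (resultant 1 g) to impact speed `v = √(2gh)`; a half-sine deceleration
pulse of angular frequency ω (surface-stiffness surrogate) and duration
π/ω whose peak `(1+e)·v·ω/2` carries exactly the impulse that reverses the
incoming momentum into a rebound at restitution `e`; a ballistic bounce and
a second absorbing pulse (the secondary collision seen in real fall
traces); rest.  The other 24 joints follow the head through a canonical
toddler skeleton (0.85 m stature) rotating smoothly from upright to the
impact posture, projected by an ideal pinhole camera.  Occlusion is
burst-structured (two-state Markov chain; stationary rate = target rate,
geometric bursts of mean 5 frames) because home occluders persist across
frames.

Ground-truth acceleration is the analytic second derivative of the head
trajectory sampled at a dedicated 2000 Hz grid — camera rates undersample
O(10 ms) pulses, and labels must not be artifacts of the video rate.
`hic_true` is the exhaustive HIC of that trace; `severity_true` its class.
Dataset scenarios are drawn with drop heights 0.05–1.2 m, ω log-uniform in
80–2500 s⁻¹ (soft-mattress to hard-floor pulse durations), restitution
0.1–0.5, at 120 frames/s, cycling the four severity classes by rejection
sampling so every class is populated.

What the simulator does *not* emulate: pose-estimator noise and systematic
detector bias, multi-person scenes, camera motion and rolling shutter,
non-vertical fall trajectories, soft-tissue dynamics.  Passing benchmarks
therefore demonstrate that the pipeline machinery is correct and that each
learned stage recovers the structure present in its input — not that the
system is validated on real home footage.

## Benchmark problem sizes

The test suite and the acceptance script train at sizes chosen to exercise
the full pipeline in minutes on one CPU: the imputer on 200 falls (8:2
train/validation, 20% burst occlusion, hidden size 64, 80 epochs, window
64) against the per-joint linear-interpolation baseline; the lifter on
5000 frames subsampled from 60 falls (15 epochs) against the
mean-training-pose baseline; the end-to-end sweep on a 7-point drop-height
grid × 10 clips at ω = 150 s⁻¹ and 10% occlusion; the severity classifier
on 600 stratified analytic traces (8:2 split).

## Known limitations

* **Video-rate HIC attenuation.** Differentiating a 120 Hz trajectory
  cannot resolve millisecond-scale pulses, so the assessed HIC
  systematically underestimates the true pulse HIC on stiff surfaces; it
  remains strongly rank-correlated with fall energy, which is what the
  end-to-end benchmark asserts.  At higher frame rates, lifting jitter
  (amplified by fps²) becomes the binding constraint instead.
* **Occlusion noise floor.** Imputed joints carry pixel-scale errors that
  double differencing turns into spurious acceleration spikes.  At 120 fps
  the attenuated impact signal stays above this floor up to roughly 10%
  burst occlusion; at 20% the assessed HIC of soft-to-moderate impacts is
  jitter-dominated and its ranking across fall heights becomes unreliable.
  The end-to-end sweep therefore runs at 10% occlusion; the imputation
  benchmark itself runs at the full 20%.
* The TP/FP/TN/FN convention treats a wrong-injury-class prediction as a
  false negative; metrics are not symmetric across classes.
* The classifier features are derived from the same trace the HIC itself
  summarizes: the classifier adds robustness, not independent evidence.
* Absolute depth, and hence absolute (not relative) lateral motion, is
  unobservable from the single view.
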