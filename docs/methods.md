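# Methods

## Problem

A wearable-sensor system on the right leg reports sagittal-plane joint
angles for the pelvis, hip, knee and ankle at 25–100 Hz. The task is
sequence labelling over seven classes — three steady postures
(standing, walking, sitting) and four short transition phases: sitting
down (`sd`), standing up (`su`), starting to walk (`stw`) and stopping
walking (`spw`) — with particular emphasis on *when* a transition is
detected, not only whether each timestep is classified correctly. The
transition classes last 0.5–1 s while steady segments last ~15 s, so
the label distribution is heavily imbalanced (each transition class is
under 5 % of samples).

## Synthetic sessions

Real recordings of this kind are typically unavailable for re-analysis,
so the package ships a generator that emulates the acquisition
protocol: repeated stand–walk–stand–sit cycles with 15 s stands and
sits, 15–20 s walks, 1 s sit-down/stand-up blends and 0.5–1 s
walk-start/stop ramps. Signal morphology per segment:

* **standing / sitting** — constant poses (knee ≈ 0° standing, ≈ 90°
  sitting, scaled by a per-subject range-of-motion factor) plus i.i.d.
  Gaussian sensor noise, default SD 0.5°, below the static accuracy of
  typical IMU orientation filters;
* **walking** — one or two sinusoidal harmonics per joint around a
  ~1.1 s stride period with joint-specific phase offsets (hip ±25°,
  knee a raised-cosine flexion bump up to ~60° with a second harmonic,
  ankle ±15°, pelvis ±4° sway). The phase runs continuously across a
  whole stw–walk–spw bout;
* **sd / su** — minimum-jerk (quintic) blends between the standing and
  sitting poses, so velocity and acceleration are zero at both ends;
* **stw / spw** — linear ramps of the gait-oscillation amplitude away
  from / back to the standing pose.

Labels switch on the first sample of each new segment (half-open
intervals); segment boundaries are cumulative-time rounded so label
runs exactly tile `round(rate × total_time)` samples. Cohorts jitter
stride period, amplitudes and overall scale multiplicatively
(SD 10 %, clipped to ±30 %) with per-subject seeds.

What the generator does **not** emulate: frontal/transverse-plane
angles, stride-to-stride variability within a walk bout, sensor drift
and soft-tissue artefacts, hesitant or compound transitions, and the
inter-joint coupling patterns of real gait beyond what the fixed
phase offsets produce. Passing results on these signals therefore
demonstrate that the pipeline's mechanics are correct and that the
architecture can exploit clean kinematic structure; they do not certify
accuracy levels on real recordings.

## Features

The network input is an n × 12 matrix: for each joint, the angle (deg)
and its first and second time derivatives (deg/s, deg/s²), computed by
central differences with first-order one-sided stencils at the two
boundary samples (keeps the feature rows aligned with the label
track). Features are z-scored per column with statistics fit on the
training subject only.

Angles are low-pass filtered before differentiation (zero-phase
Butterworth, 2nd order, 6 Hz cutoff — the standard pre-conditioning
for lower-limb kinematics; gait content lives below ~6 Hz). This
matters: double differencing amplifies white sensor noise by the
square of the sampling rate, so without the filter the acceleration
channels at 100 Hz are noise-dominated (knee-acceleration SNR ≈ 0.2
at 100 Hz vs ≈ 2.8 at 25 Hz on default-noise sessions) — a
rate-dependent artifact that real acquisition pipelines, whose
derivative outputs are visibly smooth, do not exhibit, and one that
would bias any 25-vs-100 Hz comparison. With the filter the SNR is
comparable at both rates (≈ 5 on acceleration). The cutoff is
configurable and `None` disables smoothing.

Rate comparisons use plain integer decimation without an anti-alias
filter: the decimated stream stands in for a sensor natively sampling
at the lower rate, which is the comparison of interest.

## Networks

Two families, implemented in NumPy with manual backpropagation
(gradients validated against central finite differences in the test
suite) because the training loop, not a framework, is part of what is
under test here:

* **FNN** — three fully connected layers (12→7→7→7) with no
  intermediate nonlinearity, closed by a softmax, applied independently
  per timestep: effectively a linear per-sample classifier.
* **LSTM variants** — a 2-layer stacked LSTM (hidden size 64 by
  default; the size is a free choice, small enough for a desk CPU)
  surrounded by dropout / fully connected / batch-normalization /
  leaky-ReLU layers in five different orders (Groups 1–5), an ablation
  of layer placement. Fully connected layers always output 7 nodes;
  every variant ends in a 7-class softmax. Group 5 is
  LSTM → FC → BatchNorm → Dropout(0.8) → FC → LeakyReLU → Softmax.

Training follows the printed configuration: Adam (the optimizer family
is our choice; only the rate and decay are given) with learning rate
0.001, L2 weight decay 1e-5, batch size 10, cross-entropy loss in nats
with predictions clamped at 1e-12 before the log. Sessions are cut
into non-overlapping 4 s windows with per-timestep (many-to-many)
targets; the first 70 % of windows train and the last 30 % validate
(chronological, to avoid leaking future context backwards). Everything
is deterministic given the build seed (weight init, dropout) and the
config seed (shuffling).

Full-length sessions are scored in 2000-sample chunks with 200 samples
of discarded left run-in so the recurrent state is warmed up at every
retained sample; the chunked and single-pass decodings agree to
>99.5 % of timesteps in tests.

Decoding is per-row argmax with ties broken to the lowest class index.

## Transition timing

Predicted tracks are debounced before event extraction: runs shorter
than `min_run` (default 0.2 s — comfortably below the 0.5 s minimum
real transition, so genuine events survive) are absorbed into the
preceding run (a short leading run joins the following one). Each
remaining label change is an event timestamped at the first sample of
the new run. Predicted events are matched greedily nearest-in-time,
one-to-one, to true events with the same target label, within
`max_gap`. The default cap is half the shortest spacing between
consecutive true events *with the same target label*: only same-label
events compete during matching, so that spacing (tens of seconds in a
cyclic protocol) is what can cause a cross-occurrence mismatch. Basing
the cap on the spacing between all events (0.5–1 s, the length of a
transition segment) would censor exactly the late detections the
timing error exists to measure — detectors in this setting routinely
report changes a few tenths of a second late, which must enter ΔT as
timing error, not vanish as unmatched events.

Transition-time accuracy is
`100 × (1 − (ΣΔT + 2 s × #missed) / protocol_time)`, clipped to
[0, 100], where ΔT = |t_true − t_pred| summed over three categories:
entries into steady postures, entries into activity starts (stw, sd),
entries into activity ends (spw, su). The per-missed-event penalty
(2 s, configurable) is a design choice: without one, a detector that
reports nothing would score 100 %. The denominator is the full session
duration by default (configurable, since "protocol time" could also be
read as only the evaluated span). Classification accuracy is the
fraction of matching timesteps; the confusion matrix has true classes
as rows. Between-group comparisons use Welch (unequal-variance)
two-sample t-tests at α = 0.05; zero-variance pairs are flagged as
degenerate rather than raising.

## Study harness

All studies train on subject 1 only and evaluate on held-out synthetic
subjects, and report multi-seed medians (3 seeds by default) because
single runs of small networks are seed-sensitive. Desk-scale problem
sizes are the defaults: 6 cycles (~390 s ≈ 39 000 samples at 100 Hz),
5 held-out subjects, 30 epochs. The full 150-epoch configuration is
available through `ExperimentConfig(epochs=150)`.

A caution about the layer-ordering ablation on synthetic data: because
the generated signals make the task close to linearly separable, the
variant with the fewest layers between the LSTM and the softmax
(Group 2) tends to reach the lowest held-out prediction loss, while
the heavily regularized Group 5 (dropout 0.8 plus an extra fully
connected layer) converges more slowly without a compensating
generalization benefit; the harness shows the same ordering at 30 and
at 150 epochs. Rankings between the LSTM variants measured on these
clean signals therefore say little about their ranking on real
recordings, where the extra regularization and capacity have real
pathologies to absorb. What the package warrants is the ablation
machinery itself: per-group losses, multi-seed medians, reproducible
tables.

Experiment outputs are CSV tables plus a JSON sidecar with the config
hash and seed list; a rerun with identical config and seeds is
byte-identical.

## Numerical notes and limitations

* Forget-gate biases initialize to 1; other weights are Glorot-uniform
  from a seeded generator.
* Batch normalization normalizes over (batch × time) per feature, with
  running statistics (momentum 0.1) used at evaluation.
* The cross-entropy clamp (1e-12) makes saturated softmax outputs
  finite; the gradient is zeroed where the clamp is active.
* Checkpoints restore weights and batch-norm running statistics, not
  optimizer or dropout-RNG state; they are for inference.
* Event matching is greedy by |Δt|, not globally optimal assignment;
  with the default `max_gap` the two coincide in practice.
* On these clean synthetic signals the task is close to linearly
  separable, so architectural rankings between the LSTM variants are
  weaker evidence than on real recordings; see the discussion above on
  generator fidelity.
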