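# posturekit

Detecting *when* a person changes posture — not just which posture they
are in — from lower-limb joint kinematics. `posturekit` is a library
for people working on human activity recognition, exoskeleton control
and wearable-sensor analytics who need a tested, fully reproducible
pipeline for posture-transition-time detection:

* a **synthetic-session generator** producing labelled sagittal-plane
  joint-angle streams (pelvis, hip, knee, ankle) for scripted
  stand–walk–stand–sit protocols, with four explicit transition
  classes (`sd` sit-down, `su` stand-up, `stw` start-walk, `spw`
  stop-walk) inserted between the steady postures;
* the **n × 12 feature pipeline** (angle, angular velocity, angular
  acceleration per joint; central differences, per-column z-scoring,
  integer decimation for sampling-rate studies, channel correlations);
* **sequence classifiers** over the seven classes: a per-timestep
  linear FNN (12→7→7→7 + softmax) and five LSTM variants that place
  dropout / batch-norm / fully-connected / leaky-ReLU layers around a
  2-layer LSTM in different orders — implemented in NumPy with manual
  backpropagation, trained with Adam (lr 0.001, weight decay 1e-5,
  batch 10, cross-entropy, 7:3 chronological split);
* **transition-timing evaluation**: argmax decoding, debouncing,
  change-point extraction, one-to-one event matching, and the
  transition-time accuracy

  `acc = 100 × (1 − (Σ|ΔT| + penalty · #missed) / T_protocol)`,

  where ΔT is the gap between a true posture change and the detected
  one, summed over entries into steady postures, activity starts and
  activity ends — plus per-timestep classification accuracy, confusion
  matrices and Welch t-tests between timing categories;
* a **study harness** (`posturekit.experiments` and the `posturekit`
  CLI) for the FNN-vs-LSTM, 25-vs-100 Hz, layer-ordering-ablation and
  cross-subject-generalization experiments, with seeded, byte-identical
  reruns.

## Worked example

```python
from posturekit import NetworkSpec, generate_cohort
from posturekit.experiments import ExperimentConfig, train_and_evaluate

config = ExperimentConfig(n_cycles=2, epochs=10, hidden_units=16)
cohort = generate_cohort(2, seed=0, n_cycles=2)        # two synthetic subjects
spec = NetworkSpec(kind="lstm", group_id=5, hidden_units=16)
ev = train_and_evaluate(cohort[0], cohort[1:], spec, config.training_config(seed=0))
print(ev.reports[0].summary())
```

Running the equivalent script `examples/03_train_and_detect.py` prints

```
final training loss     : 1.5925 nats
final validation loss   : 1.1499 nats
classification accuracy : 94.05 %  (per-timestep)
transition-time accuracy: 86.45 %
mean |DeltaT|           : 0.246 s over 7 matched events
```

i.e. this deliberately small demo detector (hidden size 16, 10 epochs,
one 2-cycle training session) already labels 94 % of timesteps of an
unseen subject correctly and reports posture changes about 0.25 s from
the true instant; the transition-time accuracy discounts the summed
timing gaps (plus a 2 s penalty per missed transition) against the
session duration. The full-size detector (hidden 64, 6-cycle training
session, 30 epochs) reaches ~96 % classification accuracy and
~0.17 s mean |ΔT| on held-out subjects — see below.

The other scripts in `examples/` walk through session simulation,
feature correlations and the behaviour of the timing metric. The same
functionality is scriptable from the shell:

```bash
posturekit simulate --cycles 2 --rate 100 --seed 0 --out session.csv
posturekit train --session session.csv --group 5 --epochs 30 --out model.npz
posturekit evaluate --session session.csv --model model.npz --out report/
posturekit study --study ablation --out results/ablation/
```

## Documentation

`docs/methods.md` describes the signal model, the network and training
details, the timing metric's conventions (debouncing, matching,
penalties) and the known limitations of the synthetic data.
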