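"""How the transition-time accuracy metric behaves.

Scores ground truth against itself (perfect detector) and against a
version delayed by 40 samples, showing how every DeltaT and every
missed event erodes the accuracy.
"""

import numpy as np

from posturekit import GaitParameters, make_protocol, score_predictions, synthesize_session

session = synthesize_session(make_protocol(1, rng_seed=2), GaitParameters(seed=2), 100.0)
labels = session.labels

perfect = score_predictions(labels, labels.copy(), rate=session.rate)
print(f"perfect detector : transition-time accuracy {perfect.transition_time_accuracy:.2f} %, "
      f"classification {perfect.classification_accuracy:.2f} %")

k = 40  # 0.40 s delay at 100 Hz
delayed = np.concatenate([np.full(k, labels[0]), labels[:-k]])
rep = score_predictions(labels, delayed, rate=session.rate, max_gap=1.0)
print(f"0.40 s delay     : every matched DeltaT = {rep.mean_delta_t:.2f} s, "
      f"accuracy {rep.transition_time_accuracy:.2f} %")
print(rep.category_summary().to_string(index=False))
print("entries into steady postures, into activity starts (stw/sd) and into")
print("activity ends (spw/su) are summed separately before the discount.")
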