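"""Simulate one labelled stand-walk-stand-sit session.

Builds a two-cycle activity protocol (stand 15 s, walk 15-20 s, stand
15 s, sit 15 s, with ~0.5-1 s transition phases), renders it into
100 Hz sagittal joint-angle streams and prints how the seven classes
tile the timeline.
"""

import numpy as np

from posturekit import GaitParameters, LABEL_NAMES, make_protocol, synthesize_session

protocol = make_protocol(n_cycles=2, rng_seed=0)
session = synthesize_session(protocol, GaitParameters(seed=0), rate=100.0)

print(f"protocol: {protocol.total_time:.1f} s, {len(protocol.timeline)} segments")
print(f"session: {session.n_samples} samples at {session.rate:g} Hz")
counts = np.bincount(session.labels, minlength=7)
for name, c in zip(LABEL_NAMES, counts):
    print(f"  {name:>8}: {c:6d} samples ({100 * c / session.n_samples:5.2f} %)")
print("the four transition classes are rare (a few percent each) -- the")
print("class imbalance a transition detector has to cope with.")
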