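import numpy as np
import pytest

from posturekit import GaitParameters, Label, make_protocol, synthesize_session

#: fixed transition durations used by the deterministic protocol fixtures
FIXED_TRANSITIONS = {
    Label.SD: 1.0,
    Label.SU: 1.0,
    Label.STW: 0.5,
    Label.SPW: 0.5,
}


@pytest.fixture
def one_cycle_protocol():
    """One stand-walk-stand-sit cycle with all durations fixed (63 s)."""
    return make_protocol(
        1,
        rng_seed=0,
        walk_duration_range=(15.0, 15.0),
        transition_durations=FIXED_TRANSITIONS,
    )


@pytest.fixture
def one_cycle_session(one_cycle_protocol):
    """A 63 s session at 100 Hz with the default noise level."""
    return synthesize_session(one_cycle_protocol, GaitParameters(seed=7), 100.0)


@pytest.fixture
def quiet_params():
    """Noise-free gait parameters for analytic checks."""
    return GaitParameters(noise_sd=0.0, seed=0)
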