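import numpy as np
import pytest

from affpriming import SimParams, make_schedule, simulate_epochs


@pytest.fixture(scope="session")
def forward_schedule():
    return make_schedule("forward", 400, seed=1)


@pytest.fixture(scope="session")
def noiseless_params():
    return SimParams(noise_sd=0.0, blink_rate=0.0).with_effects("forward")


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_params):
    """Five participants of noiseless forward epochs with the default P8 effect."""
    return [
        simulate_epochs(make_schedule("forward", 40, seed=10 + i),
                        noiseless_params, seed=20 + i)
        for i in range(5)
    ]


@pytest.fixture(scope="session")
def blink_recording():
    """Small continuous forward recording with blinks, shared across
    preprocessing tests (ICA is the expensive step)."""
    from affpriming import simulate_eeg
    sched = make_schedule("forward", 24, seed=3)
    params = SimParams(blink_rate=0.15).with_effects("forward")
    return simulate_eeg(sched, params, seed=5)
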