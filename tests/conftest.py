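import numpy as np
import pytest

import polystage as ps


@pytest.fixture(scope="session")
def small_record():
    """A 40-epoch clean synthetic record with its hypnogram (seeded)."""
    scenario = ps.scenario_preset("severe_osa", n_epochs=40, seed=7)
    record, hyp, _ = ps.generate_record(scenario)
    return record, hyp


@pytest.fixture(scope="session")
def sine_record():
    """Five-channel record carrying a known 5 Hz sine, 60 s at 200 Hz."""
    rate, dur = 200.0, 60.0
    t = np.arange(int(rate * dur)) / rate
    chans = []
    for i, role in enumerate(ps.ROLES):
        amp = 20.0 + 5.0 * i
        chans.append(ps.Channel(f"ch{i}", role, amp * np.sin(2 * np.pi * 5 * t), rate))
    return ps.PSGRecord(chans, dur)
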