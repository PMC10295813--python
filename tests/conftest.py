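import numpy as np
import pytest

import breathtrack as bt


@pytest.fixture(scope="session")
def stationary_profile():
    """Noise-free, drift-free breathing with no condition modulation."""
    return bt.BreathingProfile(
        base_frequency=0.21,
        frequency_drift_sd=0.0,
        amplitude_drift_sd=0.0,
        noise_sd=0.0,
        condition_frequency_offsets={},
        condition_amplitude_offsets={},
    )


@pytest.fixture(scope="session")
def perfect_session(stationary_profile):
    """Five-condition run with an error-free agent on stationary breathing."""
    agent = bt.AgentProfile(transduction_lag_ms=200.0, jitter_sd_ms=0.0, miss_rate=0.0)
    design = bt.SessionDesign(block_duration_s=30.0)
    return bt.generate_session(stationary_profile, agent, design, seed=3)


@pytest.fixture(scope="session")
def default_session():
    """Realistic run: drifting noisy breathing, imperfect agent."""
    return bt.generate_session(
        bt.BreathingProfile(), bt.AgentProfile(), bt.SessionDesign(block_duration_s=30.0), seed=11
    )


@pytest.fixture()
def sine_trace():
    """Pure 0.2 Hz unit sinusoid, 60 s at 500 Hz, starting at a trough."""
    rate, dur, f = 500.0, 60.0, 0.2
    t = np.arange(int(dur * rate)) / rate
    return bt.RespirationTrace(np.sin(2 * np.pi * f * t - np.pi / 2), rate)
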