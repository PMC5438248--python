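import numpy as np
import pandas as pd
import pytest

from paincode import GeneratorConfig, SpikeSession, generate_mixed_session


def make_session(spike_rows, trial_rows, session_id="toy", window_s=5.0):
    """Hand-built session from (unit, trial, t) rows and (trial, stimulus) rows."""
    spikes = pd.DataFrame(spike_rows, columns=["unit_id", "trial_id", "t_s"])
    trials = pd.DataFrame(trial_rows, columns=["trial_id", "stimulus",
                                               "withdrawal_latency_s", "laser_mW"])
    units = sorted(spikes["unit_id"].unique()) or ["u0"]
    return SpikeSession(session_id=session_id, units=units, spikes=spikes,
                        trials=trials, window_s=window_s)


@pytest.fixture
def small_mixed_session():
    """A quick 5-unit LS/HS session with 8 trials per class."""
    cfg = GeneratorConfig(n_units=5, n_trials_mixed=8, rng_seed=0)
    return generate_mixed_session(cfg, ("LS", "HS"), seed=42, session_id="mix")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
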