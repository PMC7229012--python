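"""Shared fixtures: small simulated sessions reused across test modules."""

import numpy as np
import pytest

from riskdecode import BehaviourPolicy, SensorModel, TaskConfig
from riskdecode.sensors import default_blink_loadings
from riskdecode.workflows import acf_cluster_pipeline, simulate_session

#: policy with longer token handling, which balances the P/N outcome classes
#: (the default policy reproduces the strongly imbalanced outcome table of
#: the task; the balanced variant is the high-SNR regime for recovery tests)
BALANCED_POLICY = BehaviourPolicy(time_at_token_mean=0.30)

SMALL_TASK = TaskConfig(n_training_trials=4, n_blocks=1, trials_per_block=81)


@pytest.fixture(scope="session")
def blink_session():
    """One participant's session with blinks planted on 140 of 275 channels."""
    model = SensorModel(
        blink_rate=0.2,
        blink_channel_loadings=default_blink_loadings(275, 140, amplitude=5.0, seed=1),
    )
    return simulate_session(
        config=SMALL_TASK, policy=BALANCED_POLICY, sensor_model=model, seed=11
    )


@pytest.fixture(scope="session")
def dwell_pipeline():
    """Decoded-dynamics pipeline on a session with planted 100-ms dwells."""
    model = SensorModel(dwell_low_ms=100.0, dwell_high_ms=100.0)
    config = TaskConfig(n_training_trials=4, n_blocks=2, trials_per_block=108)
    session = simulate_session(
        config=config, policy=BALANCED_POLICY, sensor_model=model, seed=21
    )
    pipeline = acf_cluster_pipeline(session, seed=21)
    pipeline["session"] = session
    return pipeline


@pytest.fixture(scope="session")
def sharp_evoked_session():
    """High-SNR latency-recovery conditions: narrow evoked kernel, balanced
    outcome classes."""
    model = SensorModel(evoked_kernel_width_ms=25.0)
    return simulate_session(
        config=SMALL_TASK, policy=BALANCED_POLICY, sensor_model=model, seed=31
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
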