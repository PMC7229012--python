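"""End-to-end convenience pipelines built from the module primitives.

These wire the stages together the way a full analysis would run them:
simulate a session, preprocess and epoch it, train the classifier suite,
decode the deliberation epochs and run the temporal-structure tests.  They
exist so that scripted analyses, the test-suite recovery checks and the
command-line interface all execute the identical pipeline.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .classifier import build_classifier_suite
from .dynamics import (
    autocorrelation_curve,
    cluster_permutation_test,
    decode,
    dwell_and_transition_tests,
    map_states,
)
from .preprocessing import extract_baseline, extract_epochs, preprocess_continuous, select_channels
from .sensors import SensorModel, simulate_recording
from .task import BehaviourPolicy, TaskConfig, simulate_task


def simulate_session(
    config: Optional[TaskConfig] = None,
    policy: Optional[BehaviourPolicy] = None,
    sensor_model: Optional[SensorModel] = None,
    seed: int = 0,
    participant_id: int = 0,
    n_keep: int = 135,
    baseline_n: int = 100,
) -> dict:
    """Simulate one participant's session and run it through preprocessing.

    Returns a dict with the trial table, recording, ground truth, channel
    selection and the four epoch sets (channel-selected).
    """
    config = config or TaskConfig()
    policy = policy or BehaviourPolicy()
    sensor_model = sensor_model or SensorModel()
    trials = simulate_task(config, policy, seed)
    rec, truth = simulate_recording(trials, sensor_model, seed + 90001)
    rec = preprocess_continuous(rec)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # blink-free simulations are routine here
        selection = select_channels(rec, n_keep=n_keep)
    epochs = {
        kind: extract_epochs(rec, trials, kind, channels=selection.retained,
                             participant_id=participant_id)
        for kind in ("outcome", "trial_start", "token")
    }
    epochs["baseline"] = extract_baseline(
        rec, trials, n=baseline_n, seed=seed + 90002, channels=selection.retained,
        participant_id=participant_id,
    )
    return dict(
        trials=trials,
        recording=rec,
        truth=truth,
        selection=selection,
        epochs=epochs,
    )


def acf_cluster_pipeline(
    session: dict,
    bin_star: int = 31,
    lam: float = 0.025,
    n_permuted: int = 100,
    max_lag_ms: float = 500.0,
    seed: int = 0,
    epoch_kind: str = "trial_start",
) -> dict:
    """Train the suite and run the autocorrelation cluster test.

    Decodes the deliberation epochs with the true P-vs-N classifier and
    with every permuted-label variant, computes the trial-averaged ACFs,
    and tests the observed ACF against the permuted ensemble at the
    cluster level.
    """
    suite = build_classifier_suite(
        session["epochs"]["outcome"],
        session["epochs"]["baseline"],
        bin_star,
        lam,
        seed=seed,
        n_permuted=n_permuted,
    )
    entry = suite["P_vs_N"]
    delib = session["epochs"][epoch_kind]
    observed_series = decode(entry["model"], delib)
    obs_acf = autocorrelation_curve(observed_series, max_lag_ms)
    null_series = [decode(m, delib) for m in entry["permuted"]]
    null_acf = np.array([autocorrelation_curve(s, max_lag_ms) for s in null_series])
    result = cluster_permutation_test(obs_acf, null_acf, bin_width_ms=delib.bin_width_ms)
    return dict(
        suite=suite,
        series=observed_series,
        null_series=null_series,
        acf=obs_acf,
        null_acf=null_acf,
        cluster_result=result,
    )


def dwell_transition_pipeline(pipeline: dict) -> dict:
    """Dwell-duration and transition statistics from a decoded pipeline run."""
    counts = pipeline["suite"]["training_counts"]
    observed = map_states(pipeline["series"], counts["P"], counts["N"])
    nulls = [map_states(s, counts["P"], counts["N"]) for s in pipeline["null_series"]]
    tests = dwell_and_transition_tests(observed, nulls)
    return dict(observed=observed, nulls=nulls, tests=tests)
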