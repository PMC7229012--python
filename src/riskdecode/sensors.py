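"""Synthetic multichannel sensor data with known planted structure.

The generator emulates the statistical structure the decoding analysis
assumes, on a 275-channel magnetometer-like array sampled at 100 Hz
(optionally 600 Hz to exercise the filtering path):

* outcome-locked evoked responses: a Gaussian-bump activation of a
  fixed unit-norm spatial pattern (one per outcome), peaking 310 ms after
  outcome onset;
* deliberation-period representation: a renewal process alternating
  between the two outcome patterns, with dwell durations drawn from a
  configurable distribution (default uniform 40-150 ms) and the identity of
  each dwell drawn from a logistic bias in loss magnitude and choice;
* eyeblink artefacts loading on a channel subset at Poisson times;
* additive white (optionally AR(1)) Gaussian channel noise.

Everything planted is returned in a ground-truth sidecar so downstream
stages can be tested by recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("pattern vector has zero norm")
    return v / n


def make_patterns(n_channels: int, seed: int = 0):
    """Two orthogonal unit-norm spatial patterns (Gram-Schmidt on Gaussians)."""
    rng = np.random.default_rng(seed)
    p = _unit(rng.standard_normal(n_channels))
    q = rng.standard_normal(n_channels)
    q = _unit(q - (q @ p) * p)
    return p, q


def default_blink_loadings(
    n_channels: int = 275, n_blink_channels: int = 100, amplitude: float = 5.0, seed: int = 0
) -> np.ndarray:
    """Blink topography: loadings on the first ``n_blink_channels`` channels."""
    rng = np.random.default_rng(seed)
    loadings = np.zeros(n_channels)
    loadings[:n_blink_channels] = amplitude * (0.5 + rng.random(n_blink_channels))
    return loadings


@dataclass
class SensorModel:
    """Parameters of the sensor-data generator.

    Amplitudes are in noise-standard-deviation units per channel; with the
    defaults the evoked response projects at twice the noise floor along its
    pattern and the deliberation representation at the noise floor, which
    yields realistic single-trial decodability (well below ceiling).
    """

    n_channels: int = 275
    fs: float = 100.0
    pattern_P: Optional[np.ndarray] = None
    pattern_N: Optional[np.ndarray] = None
    evoked_peak_latency_ms: float = 310.0
    evoked_kernel_width_ms: float = 50.0
    evoked_amplitude: float = 4.0
    delib_amplitude: float = 2.5
    #: uniform dwell bounds in ms; set equal for a point mass
    dwell_low_ms: float = 40.0
    dwell_high_ms: float = 150.0
    #: P(dwell is P) = sigmoid(bias_intercept - bias_mag_coef * magnitude
    #:                         + bias_choice_coef * [choice == approach])
    bias_intercept: float = 1.0
    bias_mag_coef: float = 0.3
    bias_choice_coef: float = 0.5
    noise_sd: float = 1.0
    ar_coef: float = 0.0
    blink_channel_loadings: Optional[np.ndarray] = None
    #: convenience for config files: generate default loadings on this many
    #: channels when no explicit loading vector is given
    n_blink_channels: int = 0
    blink_rate: float = 0.0
    blink_width_ms: float = 100.0
    pattern_seed: int = 0

    def validate(self) -> None:
        if self.fs not in (100.0, 600.0):
            raise ValueError(f"fs must be 100 or 600 Hz, got {self.fs}")
        if self.dwell_low_ms <= 0 or self.dwell_high_ms < self.dwell_low_ms:
            raise ValueError("dwell bounds must satisfy 0 < low <= high")
        if self.noise_sd < 0 or self.blink_rate < 0:
            raise ValueError("noise_sd and blink_rate must be non-negative")
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in (-1, 1)")

    def resolved_patterns(self):
        if self.pattern_P is None or self.pattern_N is None:
            return make_patterns(self.n_channels, self.pattern_seed)
        return _unit(np.asarray(self.pattern_P, float)), _unit(np.asarray(self.pattern_N, float))

    def dwell_state_probability(self, magnitude: int, choice: str) -> float:
        z = (
            self.bias_intercept
            - self.bias_mag_coef * magnitude
            + self.bias_choice_coef * (1.0 if choice == "approach" else 0.0)
        )
        return 1.0 / (1.0 + math.exp(-z))


@dataclass
class SensorRecording:
    """Continuous channels x samples array with typed event annotations.

    ``annotations`` has columns ``time`` (s), ``kind`` and ``trial_id``
    (-1 for events not tied to a trial, e.g. blinks).
    """

    data: np.ndarray
    fs: float
    annotations: pd.DataFrame

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if len(self.annotations):
            tmax = self.annotations["time"].max()
            tmin = self.annotations["time"].min()
            if tmin < 0 or tmax > self.duration:
                raise ValueError("annotation outside recording")


@dataclass
class GroundTruth:
    """Everything planted in a synthetic recording.

    ``schedule`` has one row per deliberation dwell: trial_id, start, end
    (s), state in {P, N}.  ``blinks`` has one row per blink event.
    """

    schedule: pd.DataFrame
    pattern_P: np.ndarray
    pattern_N: np.ndarray
    blinks: pd.DataFrame
    blink_channels: np.ndarray
    evoked_amplitude: float
    delib_amplitude: float


def _gaussian_bump(center_idx: int, width_samples: float, n_samples: int):
    """Unit-peak Gaussian kernel support and values, clipped to the record."""
    half = int(math.ceil(4 * width_samples))
    lo = max(0, center_idx - half)
    hi = min(n_samples, center_idx + half + 1)
    idx = np.arange(lo, hi)
    return idx, np.exp(-0.5 * ((idx - center_idx) / width_samples) ** 2)


def simulate_recording(trials: pd.DataFrame, model: SensorModel, seed: int):
    """Render a trial table into a continuous recording plus ground truth.

    Deliberation dwells are drawn from trial start until movement onset (or
    token offset if the player never moves); each dwell projects one outcome
    pattern at ``delib_amplitude``.  P and N outcomes add an evoked bump of
    the corresponding pattern.  Returns ``(SensorRecording, GroundTruth)``.
    """
    if trials is None or not len(trials):
        raise ValueError("trial table is empty")
    model.validate()
    rng = np.random.default_rng(seed)
    fs = model.fs
    pattern_P, pattern_N = model.resolved_patterns()

    duration = float(trials["trial_end"].iloc[-1] + trials["iti"].iloc[-1] + 1.0)
    n_samples = int(round(duration * fs)) + 1
    n_ch = model.n_channels

    if model.noise_sd > 0:
        data = rng.standard_normal((n_ch, n_samples)) * model.noise_sd
        if model.ar_coef != 0.0:
            # AR(1) over time per channel, stationary innovation scaling
            from scipy.signal import lfilter

            data = lfilter([math.sqrt(1 - model.ar_coef**2)], [1, -model.ar_coef], data, axis=1)
    else:
        data = np.zeros((n_ch, n_samples))

    annotations = []
    schedule_rows = []
    width_samples = model.evoked_kernel_width_ms / 1000.0 * fs
    peak_s = model.evoked_peak_latency_ms / 1000.0

    for row in trials.itertuples(index=False):
        annotations.append((row.trial_start, "trial_start", row.trial_id))
        annotations.append((row.token_onset, "token_on", row.trial_id))
        annotations.append((row.token_offset, "token_off", row.trial_id))
        if not np.isnan(row.movement_onset):
            annotations.append((row.movement_onset, "movement", row.trial_id))
        if row.outcome in ("P", "N"):
            annotations.append((row.outcome_onset, f"outcome_{row.outcome}", row.trial_id))
            pat = pattern_P if row.outcome == "P" else pattern_N
            center = int(round((row.outcome_onset + peak_s) * fs))
            idx, bump = _gaussian_bump(center, width_samples, n_samples)
            data[:, idx] += model.evoked_amplitude * np.outer(pat, bump)

        delib_end = row.movement_onset if not np.isnan(row.movement_onset) else row.token_offset
        p_state = model.dwell_state_probability(row.loss_magnitude, row.choice)
        t = row.trial_start
        while t < delib_end - 1e-12:
            dwell = rng.uniform(model.dwell_low_ms, model.dwell_high_ms) / 1000.0
            end = min(t + dwell, delib_end)
            state = "P" if rng.random() < p_state else "N"
            pat = pattern_P if state == "P" else pattern_N
            i0, i1 = int(round(t * fs)), int(round(end * fs))
            data[:, i0:i1] += model.delib_amplitude * pat[:, None]
            schedule_rows.append((row.trial_id, t, end, state, dwell * 1000.0))
            t = end

    blink_channels = np.array([], dtype=int)
    blink_rows = []
    loadings_spec = model.blink_channel_loadings
    if loadings_spec is None and model.n_blink_channels > 0:
        loadings_spec = default_blink_loadings(
            model.n_channels, model.n_blink_channels, seed=model.pattern_seed
        )
    if model.blink_rate > 0 and loadings_spec is not None:
        loadings = np.asarray(loadings_spec, float)
        blink_channels = np.flatnonzero(loadings)
        n_blinks = rng.poisson(model.blink_rate * duration)
        times = np.sort(rng.uniform(0, duration, n_blinks))
        bw = model.blink_width_ms / 1000.0 * fs
        for bt in times:
            idx, bump = _gaussian_bump(int(round(bt * fs)), bw, n_samples)
            data[:, idx] += np.outer(loadings, bump)
            annotations.append((bt, "blink", -1))
            blink_rows.append((bt,))

    ann = pd.DataFrame(annotations, columns=["time", "kind", "trial_id"]).sort_values(
        "time", kind="stable", ignore_index=True
    )
    rec = SensorRecording(data=data, fs=fs, annotations=ann)
    rec.validate()
    truth = GroundTruth(
        schedule=pd.DataFrame(
            schedule_rows, columns=["trial_id", "start", "end", "state", "drawn_ms"]
        ),
        pattern_P=pattern_P,
        pattern_N=pattern_N,
        blinks=pd.DataFrame(blink_rows, columns=["time"]),
        blink_channels=blink_channels,
        evoked_amplitude=model.evoked_amplitude,
        delib_amplitude=model.delib_amplitude,
    )
    return rec, truth
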