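"""Continuous-data conditioning, channel selection and epoching.

Recordings acquired at 600 Hz are zero-phase high-pass filtered at 0.5 Hz,
notch filtered at 50 Hz and resampled to the 100 Hz analysis rate; data
already at 100 Hz pass through unchanged.  Channel selection retains the
fixed-size subset of channels least contaminated by eyeblinks, scored by
the power of the blink-locked average.  Epoching produces four kinds of
epoch sets on non-overlapping data stretches:

==============  =======================  ==========================================
kind            window (ms, half-open)   exclusions
==============  =======================  ==========================================
``outcome``     [0, 750) from outcome    only P / N outcomes of approach trials
``trial_start`` [0, 1500) from start     token or movement within the window
``token``       [0, 300) from token on   movement or token offset within the window
``baseline``    single 10-ms bins        drawn from ITIs longer than 2000 ms only
==============  =======================  ==========================================

No baseline correction is applied.  Windows are half-open [start, end) and
bin ``t`` covers [10t, 10t+10) ms relative to the locking event.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .sensors import SensorRecording

logger = logging.getLogger(__name__)

ANALYSIS_FS = 100.0
BIN_WIDTH_MS = 10.0

EPOCH_WINDOWS_MS = {
    "outcome": (0.0, 750.0),
    "trial_start": (0.0, 1500.0),
    "token": (0.0, 300.0),
}

META_COLUMNS = [
    "trial_id",
    "outcome",
    "loss_prob_level",
    "loss_magnitude",
    "choice",
    "participant_id",
]


@dataclass
class EpochSet:
    """Epochs x channels x time-bins tensor of one epoch kind."""

    kind: str
    data: np.ndarray
    fs: float
    bin_width_ms: float
    window_ms: tuple
    meta: pd.DataFrame
    channels: Optional[np.ndarray] = None

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    def at_bin(self, b: int) -> np.ndarray:
        """Epochs x channels matrix of a single time bin."""
        return self.data[:, :, b]


@dataclass
class ChannelSelection:
    """Retained channel indices plus the per-channel artifact score."""

    retained: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.retained = np.asarray(self.retained, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("artifact scores must be finite and non-negative")


def preprocess_continuous(rec: SensorRecording) -> SensorRecording:
    """High-pass 0.5 Hz, notch 50 Hz and resample 600 -> 100 Hz.

    Data already at the 100 Hz analysis rate are returned unchanged (the
    identity branch is logged); annotation times are in seconds and carry
    over directly.
    """
    if rec.fs == ANALYSIS_FS:
        logger.info("recording already at %g Hz; preprocessing is the identity", ANALYSIS_FS)
        return SensorRecording(data=rec.data, fs=rec.fs, annotations=rec.annotations)
    if rec.fs != 600.0:
        raise ValueError(f"fs must be 100 or 600 Hz, got {rec.fs}")

    sos = signal.butter(4, 0.5, btype="highpass", fs=rec.fs, output="sos")
    padlen = 3 * (2 * 2 + 1) * 10
    if rec.n_samples <= padlen:
        raise ValueError(
            f"recording too short for filter warm-up ({rec.n_samples} samples <= {padlen})"
        )
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    b, a = signal.iirnotch(50.0, Q=30.0, fs=rec.fs)
    data = signal.filtfilt(b, a, data, axis=1)
    data = signal.resample_poly(data, up=1, down=6, axis=1)
    return SensorRecording(data=data, fs=ANALYSIS_FS, annotations=rec.annotations.copy())


def select_channels(rec: SensorRecording, n_keep: int = 135) -> ChannelSelection:
    """Retain the ``n_keep`` channels least contaminated by eyeblinks.

    The per-channel score is the mean squared amplitude of the blink-locked
    average in a [0, 400) ms window after each blink annotation; the
    ``n_keep`` lowest-scoring channels are retained, ties broken by channel
    index.  With no blink events all scores are zero and the first
    ``n_keep`` channels are retained with a warning.
    """
    n_ch = rec.n_channels
    if n_keep > n_ch:
        raise ValueError(f"n_keep={n_keep} exceeds channel count {n_ch}")
    blink_times = rec.annotations.loc[rec.annotations["kind"] == "blink", "time"].to_numpy()
    win = int(round(0.400 * rec.fs))
    segments = []
    for t in blink_times:
        i0 = int(round(t * rec.fs))
        if i0 < 0 or i0 + win > rec.n_samples:
            continue
        segments.append(rec.data[:, i0 : i0 + win])
    if not segments:
        warnings.warn("no usable blink events; retaining the first channels by index")
        scores = np.zeros(n_ch)
    else:
        evoked = np.mean(segments, axis=0)
        scores = np.mean(evoked**2, axis=1)
    order = np.argsort(scores, kind="stable")  # stable: ties fall back to channel index
    retained = np.sort(order[:n_keep])
    return ChannelSelection(retained=retained, scores=scores)


def _slice_epoch(rec: SensorRecording, t_event: float, window_ms: tuple, trial_id) -> np.ndarray:
    i0 = int(round((t_event + window_ms[0] / 1000.0) * rec.fs))
    n_bins = int(round((window_ms[1] - window_ms[0]) / BIN_WIDTH_MS))
    if i0 < 0 or i0 + n_bins > rec.n_samples:
        raise ValueError(f"epoch for trial {trial_id} falls outside the recording")
    return rec.data[:, i0 : i0 + n_bins]


def extract_epochs(
    rec: SensorRecording,
    trials: pd.DataFrame,
    kind: str,
    channels: Optional[np.ndarray] = None,
    participant_id: int = 0,
) -> EpochSet:
    """Extract one epoch kind from a preprocessed recording.

    Training-block trials are never epoched.  Exclusion rules per kind are
    described in the module docstring; they depend only on event timing, not
    on condition labels.
    """
    if kind not in EPOCH_WINDOWS_MS:
        raise ValueError(f"unknown epoch kind {kind!r}")
    if rec.fs != ANALYSIS_FS:
        raise ValueError("extract_epochs expects a recording at the 100 Hz analysis rate")
    window = EPOCH_WINDOWS_MS[kind]
    win_s = (window[1] - window[0]) / 1000.0

    arrays, meta_rows = [], []
    for row in trials.itertuples(index=False):
        if row.is_training:
            continue
        if kind == "trial_start":
            if row.token_onset - row.trial_start < win_s:
                continue
            if not np.isnan(row.movement_onset) and row.movement_onset - row.trial_start < win_s:
                continue
            t_event = row.trial_start
        elif kind == "token":
            if row.token_offset - row.token_onset < win_s:
                continue
            if not np.isnan(row.movement_onset) and row.movement_onset - row.token_onset < win_s:
                continue
            t_event = row.token_onset
        else:  # outcome
            if row.outcome not in ("P", "N"):
                continue
            t_event = row.outcome_onset
        arrays.append(_slice_epoch(rec, t_event, window, row.trial_id))
        meta_rows.append(
            dict(
                trial_id=row.trial_id,
                outcome=row.outcome,
                loss_prob_level=row.loss_prob_level,
                loss_magnitude=row.loss_magnitude,
                choice=row.choice,
                participant_id=participant_id,
            )
        )

    n_bins = int(round((window[1] - window[0]) / BIN_WIDTH_MS))
    if arrays:
        data = np.stack(arrays)
    else:
        data = np.empty((0, rec.n_channels, n_bins))
    if channels is not None:
        channels = np.asarray(channels, dtype=int)
        data = data[:, channels, :]
    return EpochSet(
        kind=kind,
        data=data,
        fs=rec.fs,
        bin_width_ms=BIN_WIDTH_MS,
        window_ms=window,
        meta=pd.DataFrame(meta_rows, columns=META_COLUMNS),
        channels=channels,
    )


def retained_fraction(trials: pd.DataFrame, epochs: EpochSet) -> pd.Series:
    """Fraction of non-training trials retained, per condition cell."""
    main = trials.loc[~trials["is_training"]]
    kept = main["trial_id"].isin(epochs.meta["trial_id"])
    return kept.groupby([main["loss_prob_level"], main["loss_magnitude"]]).mean()


def extract_baseline(
    rec: SensorRecording,
    trials: pd.DataFrame,
    n: int = 100,
    seed: int = 0,
    channels: Optional[np.ndarray] = None,
    participant_id: int = 0,
) -> EpochSet:
    """Draw ``n`` single-bin baseline exemplars from long inter-trial intervals.

    Exemplars are taken at uniformly random bins within the 1000 ms
    preceding a trial start, only where the preceding ITI exceeds 2000 ms.
    """
    rng = np.random.default_rng(seed)
    t = trials.reset_index(drop=True)
    eligible_starts = [
        t.loc[j, "trial_start"] for j in range(1, len(t)) if t.loc[j - 1, "iti"] > 2.0
    ]
    if not eligible_starts:
        raise ValueError(
            "no inter-trial interval longer than 2000 ms; simulate a longer session"
        )
    n_bins_window = int(round(1.0 * rec.fs))  # 1000 ms of 10-ms bins
    arrays, meta_rows = [], []
    for _ in range(n):
        start = eligible_starts[rng.integers(len(eligible_starts))]
        b = rng.integers(n_bins_window)
        t_bin = start - 1.0 + b / rec.fs
        i0 = int(round(t_bin * rec.fs))
        arrays.append(rec.data[:, i0 : i0 + 1])
        meta_rows.append(
            dict(
                trial_id=-1,
                outcome="baseline",
                loss_prob_level="none",
                loss_magnitude=-1,
                choice="none",
                participant_id=participant_id,
            )
        )
    data = np.stack(arrays)
    if channels is not None:
        channels = np.asarray(channels, dtype=int)
        data = data[:, channels, :]
    return EpochSet(
        kind="baseline",
        data=data,
        fs=rec.fs,
        bin_width_ms=BIN_WIDTH_MS,
        window_ms=(-1000.0, 0.0),
        meta=pd.DataFrame(meta_rows, columns=META_COLUMNS),
        channels=channels,
    )
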