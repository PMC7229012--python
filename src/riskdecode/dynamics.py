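"""Temporal structure of decoded outcome representations.

The trained classifiers assign every deliberation time bin a probability
that the positive outcome is represented.  This module quantifies the
temporal structure of those probability series: trial-wise autocorrelation
functions, cluster-level permutation inference against ensembles of
permuted-label classifiers (cluster inclusion at log-likelihood > 3, where
LL is the negative log of the two-sided permutation exceedance
probability), collapse into most-likely-outcome state sequences via the
training-set base-rate threshold, and dwell-duration / transition-count
statistics against the permuted-classifier null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .classifier import ClassifierModel
from .preprocessing import EpochSet

logger = logging.getLogger(__name__)

LL_THRESHOLD = 3.0


@dataclass
class ProbSeries:
    """Trials x time-bins decoded probabilities p(positive outcome)."""

    values: np.ndarray
    kind: str
    contrast: str
    meta: pd.DataFrame
    bin_width_ms: float = 10.0
    participant_id: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values <= 0) | (self.values >= 1)):
            raise ValueError("decoded probabilities must lie strictly in (0, 1)")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterTestResult:
    """Per-lag LL values, suprathreshold clusters and the permutation null."""

    lags_ms: np.ndarray
    ll: np.ndarray
    clusters: list
    null_max_masses: np.ndarray
    threshold: float

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c["significant"]]


@dataclass
class StateSequenceStats:
    """Most-likely-outcome state sequences and their dwell structure."""

    states: np.ndarray  # trials x bins, True = positive outcome
    dwell_ms: np.ndarray  # pooled dwell durations across trials
    transitions: np.ndarray  # per-trial transition counts
    p_chance: float
    bin_width_ms: float = 10.0

    @property
    def mean_transitions(self) -> float:
        return float(np.mean(self.transitions))


def decode(model: ClassifierModel, epochs: EpochSet) -> ProbSeries:
    """Decode representation probabilities for every epoch and time bin.

    ``p = sigmoid(w . x + intercept)`` applied independently per bin.
    """
    if epochs.data.shape[1] != model.n_channels:
        raise ValueError(
            f"channel mismatch: epochs have {epochs.data.shape[1]} channels, "
            f"classifier has {model.n_channels}"
        )
    z = np.einsum("ecb,c->eb", epochs.data, model.weights) + model.intercept
    values = 1.0 / (1.0 + np.exp(-z))
    eps = np.finfo(float).tiny
    values = np.clip(values, eps, 1.0 - 1e-16)
    return ProbSeries(
        values=values,
        kind=epochs.kind,
        contrast=model.contrast,
        meta=epochs.meta.copy(),
        bin_width_ms=epochs.bin_width_ms,
        participant_id=int(epochs.meta["participant_id"].iloc[0]) if len(epochs.meta) else 0,
    )


def autocorrelation_curve(series: ProbSeries, max_lag_ms: float = 500.0) -> np.ndarray:
    """Mean trial-wise autocorrelation of the decoded probabilities.

    Each trial is demeaned and its ACF computed with biased (1/n)
    normalisation at lags 10..max_lag ms, then averaged across trials.
    Zero-variance trials are skipped (count logged); if every trial is
    degenerate an error is raised.
    """
    n_lags = int(round(max_lag_ms / series.bin_width_ms))
    if n_lags >= series.n_bins:
        raise ValueError("max_lag_ms must be shorter than the epoch")
    x = series.values - series.values.mean(axis=1, keepdims=True)
    denom = np.einsum("tb,tb->t", x, x) / series.n_bins
    good = denom > 0
    n_skipped = int((~good).sum())
    if n_skipped:
        logger.info("skipping %d zero-variance trials in autocorrelation", n_skipped)
    if not good.any():
        raise ValueError("all trials have zero variance; autocorrelation undefined")
    x = x[good]
    denom = denom[good]
    acf = np.empty((x.shape[0], n_lags))
    for k in range(1, n_lags + 1):
        acf[:, k - 1] = np.einsum("tb,tb->t", x[:, :-k], x[:, k:]) / series.n_bins / denom
    return acf.mean(axis=0)


def _ll_curve(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Per-lag negative log exceedance probability under a permutation null.

    Extremeness is the absolute deviation from the null mean (two-sided);
    the exceedance probability uses the add-one correction
    ``(r + 1) / (n + 1)`` so that LL stays finite.
    """
    mu = null.mean(axis=0)
    dev_obs = np.abs(observed - mu)
    dev_null = np.abs(null - mu)
    r = (dev_null >= dev_obs[None, :] - 1e-15).sum(axis=0)
    p_hat = (r + 1) / (null.shape[0] + 1)
    return -np.log(p_hat)


def _clusters_from_ll(ll: np.ndarray, sign: np.ndarray, threshold: float = LL_THRESHOLD):
    """Maximal runs of LL > threshold with mass = sum of member LLs."""
    above = ll > threshold
    clusters = []
    i = 0
    n = len(ll)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            clusters.append(
                dict(
                    start=i,
                    end=j,  # half-open bin-index range
                    mass=float(ll[i:j].sum()),
                    sign=int(np.sign(sign[i:j].sum())),
                )
            )
            i = j
        else:
            i += 1
    return clusters


def cluster_permutation_test(
    observed: np.ndarray,
    null_ensemble: np.ndarray,
    lags_ms: Optional[np.ndarray] = None,
    bin_width_ms: float = 10.0,
    threshold: float = LL_THRESHOLD,
) -> ClusterTestResult:
    """Cluster-level permutation test of an ACF against a permuted ensemble.

    Per lag, the two-sided exceedance probability of the observed value in
    the ensemble gives LL = -ln p_hat; clusters are maximal runs of
    LL > ``threshold`` with mass the sum of member LLs.  The null
    distribution of maximal cluster masses is built by scoring each
    ensemble member against the remaining members (leave-one-out); a
    cluster is significant when its mass exceeds the 95th percentile of
    that null.

    To keep the scheme exchangeable, each ensemble member is scored
    against the other members plus the observed curve, so that every
    analysis (observed or permuted) is referenced against an ensemble of
    the same size; without this, resolution limits of the add-one-corrected
    exceedance probability systematically favour the observed curve.
    """
    observed = np.asarray(observed, dtype=float)
    null_ensemble = np.asarray(null_ensemble, dtype=float)
    m = null_ensemble.shape[0]
    if m < 20:
        raise ValueError(f"null ensemble of {m} members gives insufficient p resolution")
    if lags_ms is None:
        lags_ms = (np.arange(observed.size) + 1) * bin_width_ms

    ll = _ll_curve(observed, null_ensemble)
    sign = observed - null_ensemble.mean(axis=0)
    clusters = _clusters_from_ll(ll, sign, threshold)

    null_max = np.zeros(m)
    for i in range(m):
        rest = np.vstack([np.delete(null_ensemble, i, axis=0), observed[None, :]])
        ll_i = _ll_curve(null_ensemble[i], rest)
        sign_i = null_ensemble[i] - rest.mean(axis=0)
        cl = _clusters_from_ll(ll_i, sign_i, threshold)
        null_max[i] = max((c["mass"] for c in cl), default=0.0)

    thr = float(np.percentile(null_max, 95))
    for c in clusters:
        c["significant"] = c["mass"] > thr
        c["start_ms"] = float(lags_ms[c["start"]])
        c["end_ms"] = float(lags_ms[c["end"] - 1])
    return ClusterTestResult(
        lags_ms=np.asarray(lags_ms, float),
        ll=ll,
        clusters=clusters,
        null_max_masses=null_max,
        threshold=thr,
    )


def map_states(series: ProbSeries, n_positive: int, n_negative: int) -> StateSequenceStats:
    """Collapse probabilities into the most likely represented outcome.

    The threshold ``p_chance`` is the positive-outcome base rate of the
    training set; a bin is labelled positive when ``p > p_chance`` (ties go
    to negative).  Dwell epochs are maximal constant runs; transitions per
    trial equal the number of dwell epochs minus one.
    """
    total = n_positive + n_negative
    if total <= 0:
        raise ValueError("training label counts must be positive")
    p_chance = n_positive / total
    if p_chance in (0.0, 1.0):
        raise ValueError("degenerate training set: p_chance is 0 or 1")
    states = series.values > p_chance
    dwells = []
    transitions = np.empty(series.n_trials, dtype=int)
    for t in range(series.n_trials):
        changes = np.flatnonzero(np.diff(states[t].astype(np.int8)))
        bounds = np.concatenate([[0], changes + 1, [series.n_bins]])
        runs = np.diff(bounds)
        dwells.append(runs * series.bin_width_ms)
        transitions[t] = len(runs) - 1
    return StateSequenceStats(
        states=states,
        dwell_ms=np.concatenate(dwells) if dwells else np.array([]),
        transitions=transitions,
        p_chance=p_chance,
        bin_width_ms=series.bin_width_ms,
    )


def dwell_and_transition_tests(
    observed: StateSequenceStats, null: Sequence[StateSequenceStats]
) -> dict:
    """Compare dwell durations and transition counts against the null ensemble.

    Dwell durations pooled over trials are compared with the pooled null
    durations by a two-sample Kolmogorov-Smirnov test.  The transition
    p-value is the lower-tail proportion of null ensemble members whose mean
    transition count is at most the observed one; when no member is as low
    the p-value is reported as an upper bound 1/n_ensemble.
    """
    if not len(null):
        raise ValueError("null ensemble is empty")
    if observed.dwell_ms.size == 0:
        raise ValueError("observed dwell sample is empty")
    null_dwells = np.concatenate([s.dwell_ms for s in null])
    ks = ks_2samp(observed.dwell_ms, null_dwells)
    null_means = np.array([s.mean_transitions for s in null])
    n = len(null_means)
    count = int((null_means <= observed.mean_transitions).sum())
    return dict(
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        transition_p=count / n if count else 1.0 / n,
        transition_p_is_upper_bound=count == 0,
        observed_mean_transitions=observed.mean_transitions,
        null_mean_transitions=float(null_means.mean()),
    )
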