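"""Generative model of the approach/avoidance foraging task.

A virtual player starts each trial in a safe grid position. After a gamma
distributed delay a reward token appears; the player may approach it at the
risk of being caught by a predator whose wake-up hazard is a Bernoulli event
in every 20-ms bin spent outside the safe position. Loss probability (three
predator types) and loss magnitude (0-5 tokens) are crossed in a balanced
3 x 6 condition grid. Each trial ends in one of four ways: a positive
outcome P (token collected and returned safely), a negative outcome N
(caught), a neutral outcome F (token vanished mid-excursion), or no outcome
when the player avoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOSS_PROB_LEVELS = ("low", "medium", "high")

DEFAULT_CATCH_PROBS = {"low": 0.02, "medium": 0.04, "high": 0.06}


@dataclass
class TaskConfig:
    """Task structure and stochastic timing parameters.

    Timing delays (token appearance, token lifetime, inter-trial interval)
    are min(cap, Gamma(shape, scale)) draws; with the default shape 2 and
    scale 1 s the uncapped mean is 2 s.
    """

    n_training_trials: int = 36
    n_blocks: int = 5
    trials_per_block: int = 108
    per_bin_catch_prob: dict = field(default_factory=lambda: dict(DEFAULT_CATCH_PROBS))
    bin_width_ms: float = 20.0
    loss_magnitudes: tuple = (0, 1, 2, 3, 4, 5)
    gamma_shape: float = 2.0
    gamma_scale: float = 1.0
    token_cap: float = 6.0
    iti_cap: float = 4.0
    #: the trial ends this long after token disappearance / outcome
    end_padding: float = 1.0

    def validate(self) -> None:
        for level, p in self.per_bin_catch_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"per-bin catch probability for {level!r} not in [0, 1]: {p}")
        for name in ("token_cap", "iti_cap", "gamma_shape", "gamma_scale", "bin_width_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if set(self.per_bin_catch_prob) != set(LOSS_PROB_LEVELS):
            raise ValueError(
                f"per_bin_catch_prob must have levels {LOSS_PROB_LEVELS}, "
                f"got {tuple(self.per_bin_catch_prob)}"
            )

    @property
    def n_trials(self) -> int:
        return self.n_training_trials + self.n_blocks * self.trials_per_block


@dataclass
class BehaviourPolicy:
    """Stochastic stand-in for a participant's behavioural policy.

    Approach probability is logistic in the condition variables,
    ``sigmoid(b0 + b_prob * prob_idx + b_mag * magnitude + b_int * prob_idx
    * magnitude)`` with prob_idx in {0, 1, 2}.  Approach latency (time from
    token appearance to leaving the safe place) is a truncated normal with
    condition-dependent mean.  Travel and token-handling times determine the
    exposure to predation.
    """

    approach_intercept: float = 3.2
    approach_prob_coef: float = -0.3
    approach_mag_coef: float = -0.5
    approach_interaction_coef: float = -0.05
    latency_base: float = 0.6
    latency_prob_coef: float = 0.05
    latency_mag_coef: float = 0.03
    latency_sd: float = 0.15
    latency_min: float = 0.35
    travel_time: float = 0.03
    time_at_token_mean: float = 0.04
    time_at_token_sd: float = 0.01

    def validate(self) -> None:
        if self.travel_time <= 0 or self.latency_min <= 0:
            raise ValueError("travel_time and latency_min must be positive")
        if self.time_at_token_mean < 0:
            raise ValueError("time_at_token_mean must be non-negative")

    def approach_probability(self, prob_idx: int, magnitude: int) -> float:
        z = (
            self.approach_intercept
            + self.approach_prob_coef * prob_idx
            + self.approach_mag_coef * magnitude
            + self.approach_interaction_coef * prob_idx * magnitude
        )
        return 1.0 / (1.0 + math.exp(-z))


def catch_probability(per_bin_prob: float, exposure_ms: float, bin_width_ms: float = 20.0) -> float:
    """Probability of at least one predator wake-up over an exposure.

    The predator wakes independently in each complete ``bin_width_ms`` bin
    with probability ``per_bin_prob``; partial trailing bins are floored
    away.  Returns ``1 - (1 - p)**floor(exposure / bin_width)``.
    """
    if not 0.0 <= per_bin_prob <= 1.0:
        raise ValueError(f"per_bin_prob not in [0, 1]: {per_bin_prob}")
    if exposure_ms < 0:
        raise ValueError(f"exposure must be non-negative, got {exposure_ms} ms")
    n_bins = int(math.floor(exposure_ms / bin_width_ms + 1e-9))
    return 1.0 - (1.0 - per_bin_prob) ** n_bins


def _balanced_conditions(n_trials: int, magnitudes: tuple, rng: np.random.Generator):
    """Condition sequence balanced over the 3 x len(magnitudes) grid.

    Full replicates of the grid are dealt first and shuffled; any remainder
    is drawn without replacement from a final shuffled replicate.
    """
    grid = [(lv, m) for lv in LOSS_PROB_LEVELS for m in magnitudes]
    cells = []
    while len(cells) + len(grid) <= n_trials:
        block = list(grid)
        rng.shuffle(block)
        cells.extend(block)
    if len(cells) < n_trials:
        block = list(grid)
        rng.shuffle(block)
        cells.extend(block[: n_trials - len(cells)])
    return cells


def simulate_task(config: TaskConfig, policy: BehaviourPolicy, seed: int) -> pd.DataFrame:
    """Simulate a full session and return the trial table.

    Returns a DataFrame with one row per trial: identifiers and conditions,
    absolute event times in seconds (trial_start, token_onset, token_offset,
    movement_onset, outcome_onset, trial_end), the choice, the outcome in
    {P, N, F, none}, the approach latency, and the inter-trial interval that
    follows the trial.
    """
    config.validate()
    policy.validate()
    rng = np.random.default_rng(seed)

    rows = []
    t = 0.0
    trial_id = 0
    for block in range(config.n_blocks + 1):
        is_training = block == 0
        n_in_block = config.n_training_trials if is_training else config.trials_per_block
        conditions = _balanced_conditions(n_in_block, config.loss_magnitudes, rng)
        for level, magnitude in conditions:
            prob_idx = LOSS_PROB_LEVELS.index(level)
            trial_start = t
            token_delay = min(config.token_cap, rng.gamma(config.gamma_shape, config.gamma_scale))
            token_onset = trial_start + token_delay
            token_dur = min(config.token_cap, rng.gamma(config.gamma_shape, config.gamma_scale))
            token_offset = token_onset + token_dur

            p_appr = policy.approach_probability(prob_idx, magnitude)
            latency = max(
                policy.latency_min,
                policy.latency_base
                + policy.latency_prob_coef * prob_idx
                + policy.latency_mag_coef * magnitude
                + policy.latency_sd * rng.standard_normal(),
            )
            approaches = rng.random() < p_appr and token_onset + latency < token_offset

            movement_onset = np.nan
            outcome = "none"
            outcome_onset = np.nan
            action_latency = np.nan
            if approaches:
                action_latency = latency
                movement_onset = token_onset + latency
                reach_time = movement_onset + policy.travel_time
                if reach_time >= token_offset:
                    # token vanished mid-travel: player turns back at offset
                    return_time = token_offset + policy.travel_time
                    pending = "F"
                else:
                    handling = max(0.0, policy.time_at_token_mean
                                   + policy.time_at_token_sd * rng.standard_normal())
                    return_time = reach_time + handling + policy.travel_time
                    pending = "P"
                # predation hazard in every complete 20-ms bin outside safety
                bin_s = config.bin_width_ms / 1000.0
                n_bins = int(math.floor((return_time - movement_onset) / bin_s + 1e-9))
                p_bin = config.per_bin_catch_prob[level]
                caught_bin = -1
                if n_bins > 0 and p_bin > 0:
                    wakes = rng.random(n_bins) < p_bin
                    hits = np.flatnonzero(wakes)
                    if hits.size:
                        caught_bin = int(hits[0])
                if caught_bin >= 0:
                    outcome = "N"
                    outcome_onset = movement_onset + (caught_bin + 1) * bin_s
                else:
                    outcome = pending
                    outcome_onset = return_time if pending == "P" else np.nan
                choice = "approach"
            else:
                choice = "avoid"

            resolved = token_offset if np.isnan(outcome_onset) else max(token_offset, outcome_onset)
            trial_end = resolved + config.end_padding
            iti = min(config.iti_cap, rng.gamma(config.gamma_shape, config.gamma_scale))

            rows.append(
                dict(
                    trial_id=trial_id,
                    block=block,
                    is_training=is_training,
                    loss_prob_level=level,
                    loss_magnitude=magnitude,
                    trial_start=trial_start,
                    token_onset=token_onset,
                    token_offset=token_offset,
                    choice=choice,
                    action_latency=action_latency,
                    movement_onset=movement_onset,
                    outcome=outcome,
                    outcome_onset=outcome_onset,
                    trial_end=trial_end,
                    iti=iti,
                )
            )
            t = trial_end + iti
            trial_id += 1

    return pd.DataFrame(rows)
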