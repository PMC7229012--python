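# riskdecode

Time-resolved decoding of probabilistic outcome representations from
MEG-like sensor data, built around an approach/avoidance foraging task.

During risky decisions, does the brain retrieve the possible outcomes of
an action one at a time? A way to ask this with electrophysiology is to
train classifiers on the sensor patterns evoked when outcomes actually
occur, then apply them during deliberation and study the *temporal
structure* of the decoded representation probabilities. `riskdecode`
implements that full analysis as a reusable, tested pipeline — and,
because recordings for this task are not publicly available, ships a
synthetic task + sensor generator with exact ground truth so every stage
is verifiable by recovery.

The pipeline:

1. **Task simulation** — a foraging game under predation: on each trial a
   reward token appears after a `min(6 s, Γ(k=2, θ=1 s))` delay; an
   approach risks capture, decided by an independent Bernoulli event in
   every 20-ms bin outside the safe position (per-bin probability 0.02 /
   0.04 / 0.06; ≈ 0.1 / 0.2 / 0.3 per 100 ms of exposure). Loss magnitude
   (0–5) and loss probability form a balanced 3 × 6 grid over 576 trials.
2. **Sensor simulation** — 275 channels at 100 Hz with planted unit-norm
   spatial patterns: outcome-evoked bumps peaking 310 ms post-outcome,
   and a deliberation-period renewal process alternating between the two
   outcome patterns (dwells 40–150 ms, identity biased by loss magnitude
   and upcoming choice), plus eyeblink artifacts and channel noise.
3. **Preprocessing** — 0.5 Hz high-pass / 50 Hz notch / downsample to
   100 Hz (for 600 Hz inputs), retention of the 135 channels with fewest
   blink artifacts, and epoching into outcome (0–750 ms, 75 × 10-ms
   bins), trial-start (0–1500 ms), token (0–300 ms) and baseline sets.
4. **Outcome classifiers** — per-time-bin lasso-regularised logistic
   regression (`mean NLL + λ‖w‖₁`, λ = 0.025 initially, then optimised by
   nested cross-validation at the group-level peak bin), scored by
   balanced accuracy `(TP/P + TN/N)/2` (chance 0.5 at any class ratio),
   plus 100 permuted-label classifiers per contrast for null
   distributions, leave-one-condition-out cross-classification, and
   per-condition accuracy curves.
5. **Decoded dynamics** — `p(P) = σ(w·x + b)` per deliberation bin;
   trial-wise autocorrelation tested against the permuted ensemble with
   cluster-level permutation inference (cluster inclusion at
   `LL = −ln p̂ > 3`); most-likely-outcome state sequences via the
   base-rate threshold `p_chance`, with dwell-duration (two-sample
   Kolmogorov–Smirnov) and transition-count permutation tests.
6. **Condition effects** — per-bin linear mixed models on
   logit-transformed probabilities (3 × 6 × 2 factorial fixed effects ×
   random subject intercept, F tests with conservative `df = N − K`),
   cluster-level permutation correction across bins, and behavioural
   mixed models (logistic for approach, linear for latency).

## Worked example

```python
from riskdecode import TaskConfig, BehaviourPolicy, SensorModel, accuracy_timecourse
from riskdecode.workflows import simulate_session, acf_cluster_pipeline, dwell_transition_pipeline

config = TaskConfig(n_training_trials=4, n_blocks=2, trials_per_block=108)
policy = BehaviourPolicy(time_at_token_mean=0.30)          # balanced outcome classes
model = SensorModel(dwell_low_ms=100.0, dwell_high_ms=100.0)  # plant 100-ms dwells

session = simulate_session(config=config, policy=policy, sensor_model=model, seed=21)
outcome = session["epochs"]["outcome"]
print(f"training epochs: {outcome.n_epochs} "
      f"(P={int((outcome.meta.outcome == 'P').sum())}, "
      f"N={int((outcome.meta.outcome == 'N').sum())})")

curve = accuracy_timecourse(outcome, lam=0.025, seed=0)
print(f"peak balanced accuracy {curve.values.max():.3f} at bin {curve.peak_bin} "
      f"({10 * curve.peak_bin} ms post-outcome)")

pipeline = acf_cluster_pipeline(session, bin_star=curve.peak_bin, seed=21)
for c in pipeline["cluster_result"].significant_clusters:
    sign = "positive" if c["sign"] > 0 else "negative"
    print(f"significant {sign} ACF cluster {c['start_ms']:.0f}-{c['end_ms']:.0f} ms "
          f"(mass {c['mass']:.1f})")

stats = dwell_transition_pipeline(pipeline)["tests"]
print(f"mean transitions per trial: {stats['observed_mean_transitions']:.1f} observed "
      f"vs {stats['null_mean_transitions']:.1f} under permuted classifiers "
      f"(p < {stats['transition_p']:.3f}); dwell KS p = {stats['ks_pvalue']:.2g}")
```

prints:

```
training epochs: 135 (P=79, N=56)
peak balanced accuracy 0.894 at bin 30 (300 ms post-outcome)
significant positive ACF cluster 10-90 ms (mass 41.5)
significant negative ACF cluster 120-150 ms (mass 14.4)
significant negative ACF cluster 170-270 ms (mass 43.0)
significant negative ACF cluster 290-340 ms (mass 25.0)
significant negative ACF cluster 360-410 ms (mass 24.7)
significant negative ACF cluster 430-500 ms (mass 36.2)
mean transitions per trial: 56.4 observed vs 73.3 under permuted classifiers (p < 0.010); dwell KS p = 4.8e-46
```

Read: the outcome classifier peaks within one bin of the planted 310-ms
evoked latency; decoded deliberation probabilities are positively
autocorrelated below the planted 100-ms dwell duration and
anticorrelated beyond it; and the decoded state sequence switches far
less often than every one of the 100 permuted-label classifiers predicts
— the signature of persistent, alternating outcome representations.

There is also a CLI mirroring the stages:

```bash
riskdecode simulate --config cfg.json --seed 7 --out sim/
riskdecode preprocess --in sim/recording.h5 --trials sim/trials.csv --out prep/
riskdecode train --epochs prep/epochs_outcome.h5 --baseline prep/epochs_baseline.h5 --out models/
riskdecode decode --models models/models.json --epochs prep/epochs_trial_start.h5 --out probs.h5
riskdecode dynamics --models models/models.json --epochs prep/epochs_trial_start.h5 --out dyn.json
```

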