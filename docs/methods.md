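# Methods

`riskdecode` implements a complete, testable analogue of a time-resolved
MEG decoding analysis of probabilistic outcome representations during
risky decision-making. Because no public recordings exist for this kind of
task, the package pairs the analysis pipeline with a synthetic generator
whose planted structure is known exactly, so every stage can be validated
by recovery rather than by eyeballing.

## Task generative model

A session consists of a training block (36 trials, never analysed)
followed by five blocks of 108 trials (576 total, 540 analysed). Loss
probability (low / medium / high) and loss magnitude (0–5 tokens) are
crossed in a 3 × 6 grid balanced exactly within every block. Token
appearance, token lifetime and the inter-trial interval are
`min(cap, Gamma(k=2, θ=1 s))` draws with caps of 6 s, 6 s and 4 s
respectively (uncapped mean 2 s). While the player is outside the safe
position, the predator wakes independently in every 20-ms bin with
probability 0.02 / 0.04 / 0.06 per level, so 100 ms of exposure yields a
catch probability of `1 − (1 − p)⁵` ≈ 0.1 / 0.2 / 0.3. Partial trailing
bins carry no hazard (exposure is floored to whole bins).

The behavioural policy is a logistic approach rule in the condition
variables plus truncated-normal latency and handling-time models. The
default policy was set to reproduce the published outcome table of this
task family: approach probability ≈ 0.96 in the most favourable cell
falling to ≈ 0.4 in the least, excursions of ~100 ms outside safety, and
a resulting P : N outcome ratio of ≈ 5.7 : 1 with ≈ 325 usable training
epochs per session. A "balanced" variant (longer token handling, hence
more negative outcomes) is used in recovery tests where classifier
quality, not realism of the imbalance, is the point.

## Sensor model

Recordings are 275 channels at 100 Hz (600 Hz mode exists to exercise the
filter path). Three planted components sit on white (optionally AR(1))
Gaussian channel noise of unit standard deviation:

* **Outcome-evoked responses** — each P or N outcome adds a unit-norm
  spatial pattern (one per outcome, orthogonal by construction) scaled by
  a Gaussian temporal kernel of width 50 ms peaking 310 ms after outcome
  onset, amplitude 4 (in noise-SD units along the pattern).
* **Deliberation-period representation** — from trial start until
  movement (or token offset), a renewal process draws dwell durations
  (default uniform 40–150 ms) and, at each renewal, an outcome identity
  from a logistic bias `P(state = P) = σ(1.0 − 0.3·magnitude +
  0.5·[approach])`; the corresponding pattern is projected at amplitude
  2.5. The renewal identities are drawn independently at each dwell; with
  an unbiased rule the process alternates in expectation, and the
  magnitude/choice bias is the planted analogue of the condition effects
  the mixed models look for.
* **Eyeblinks** — Gaussian bumps (100 ms) of a fixed loading vector over
  a configurable channel subset, at Poisson times.

Amplitudes were fixed by a variance budget: with ~70 balanced training
epochs the trained classifier's weight vector aligns ≈ 0.5 with the
planted pattern axis, putting the dwell signal at roughly a third of
decoded-score variance — strong enough that the temporal-structure tests
have power at desk scale (tens of trials), weak enough that single-trial
decoding stays far from ceiling. What the generator does *not* emulate:
realistic head geometry and forward fields, 1/f spectra, cross-channel
noise correlations, eye-movement signals beyond blinks, or
non-stationarity across a session. Passing tests therefore demonstrate
correctness and calibration of the *analysis*, not performance claims
about real recordings.

## Preprocessing

600 Hz inputs are zero-phase high-pass filtered at 0.5 Hz (4th-order
Butterworth), notch filtered at 50 Hz (Q = 30) and polyphase-resampled to
100 Hz; 100 Hz inputs pass through unchanged. Channel selection retains
the 135 channels with the smallest mean squared blink-locked average in a
0–400 ms window after blink events (ties broken by channel index). The
blink score is a deliberately simple stand-in for heavier artifact
detectors; on synthetic data the planted blink channels are known, so the
selection is tested by exact recovery.

Epochs are half-open windows of 10-ms bins with no baseline correction:
outcome 0–750 ms (75 bins), trial start 0–1500 ms (150 bins), token
0–300 ms (30 bins). Trial-start epochs are dropped if the token (or any
movement) arrives within 1500 ms; token epochs are dropped if movement or
token offset occurs before 300 ms; outcome epochs exist only for P and N.
These rules depend only on event timing, never on condition labels. One
hundred single-bin baseline exemplars are drawn uniformly from the
1000 ms preceding trial starts, restricted to inter-trial intervals
longer than 2000 ms.

## Classifiers

Each classifier minimises `mean NLL + λ‖w‖₁` with an unpenalised
intercept — the lasso-logistic convention in which λ = 0.025 is the
standard initial penalty. Fits are delegated to scikit-learn's liblinear
solver with `C = 1/(nλ)`; liblinear's intercept penalty is suppressed via
a large `intercept_scaling` and the intercept is then polished by a 1-D
Newton step to its exact unpenalised optimum given the weights. A slower
exact solver (saga) backs up the rare bins where coordinate descent
stalls near separability. The implementation is validated against an
iterated brute-force grid search of the full objective on 3-feature
problems (agreement to 1e−4).

Balanced accuracy — the mean of the two per-class accuracy rates, chance
0.5 at any class ratio — scores stratified 5-fold cross-validation
(seeded folds, held-out predictions pooled). The peak time bin is chosen
on the group-mean accuracy curve; the penalty is then optimised per
participant over 20 log-spaced values in [1e−4, 1] by cross-validated
accuracy at that bin (ties to the smaller λ). Three contrasts are trained
at the peak bin (P vs N, P vs baseline, N vs baseline), each with 100
permuted-label variants for null distributions. Cross-classification
leaves one condition level out (3 probability + 6 magnitude levels = 9
classifiers per participant) and tests group accuracies against 0.5 with
a one-sided Wilcoxon signed-rank test. Per-condition accuracy curves use
"baseline-to-peak" accuracy: the value at the peak bin minus the mean
over the first 100 ms post-outcome (a convention this package declares,
since the notion is otherwise underdetermined).

## Decoded dynamics

Decoding maps each bin's channel pattern through the logistic sigmoid of
the classifier score. The autocorrelation estimator demeans each trial,
uses biased (1/n) normalisation, and averages ACFs across trials at lags
10–500 ms (both choices configurable; pooling before correlation is
deliberately not the default).

Cluster inference follows the permutation-ensemble logic: at each lag the
two-sided exceedance of the observed ACF in the 100-member permuted
ensemble (extremeness = absolute deviation from the ensemble mean, with
the add-one correction `p̂ = (r+1)/(n+1)` so that `LL = −ln p̂` is
finite) defines a log-likelihood curve; clusters are maximal runs with
`LL > 3` and mass the sum of member LLs. The null distribution of
maximal cluster masses scores each ensemble member against *the other
members plus the observed curve*. Scoring members only against the
remaining ensemble (one fewer reference curve) leaves the observed curve
able to reach `−ln(1/(n+1))` while no null can exceed `−ln(1/n)`; at the
resolution limit this inflates the family false-positive rate several
fold, which is why the symmetric reference set is used — under the null
every analysis is then exchangeable. Significance is mass above the 95th
percentile of the null maxima.

State sequences threshold `p(P)` at the training-set base rate
`p_chance` (ties to N), giving dwell epochs (maximal constant runs) and
transition counts (dwells − 1). Dwell distributions are compared with
the pooled permuted-null dwells by a two-sample Kolmogorov–Smirnov test;
the transition p-value is the lower-tail proportion of ensemble members
with mean transitions at or below the observed, reported as an upper
bound `1/n` when none is.

## Mixed-model time courses

Decoded probabilities are logit-transformed (clipped at ε = 1e−6) and
modelled per bin with a linear mixed model: the full 3 × 6 × 2 factorial
of loss probability, loss magnitude and choice as categorical fixed
effects (treatment coding, references "low" / 0 / "approach") plus a
random per-subject intercept. The fit profiles REML over the variance
ratio σ_b²/σ²: for fixed ratio, GLS reduces to OLS on within-group
shrinkage-transformed data, leaving a 1-D criterion minimised by bounded
search. This fitter exists because the cluster permutation scheme refits
the model tens of thousands of times; it is cross-checked against
statsmodels' MixedLM in the test suite (coefficients, variance
components and covariances agree to numerical tolerance).

Per-term F statistics are Wald block tests on the term's coefficient
block, with denominator degrees of freedom conservatively set to
`N − K`, K counting all fixed coefficients plus the subject intercepts.
With treatment coding these blocks test the term's dummy coefficients
(simple effects at the reference levels rather than marginal main
effects); what the package guarantees — and what the tests verify — is
exact null calibration of the resulting p-values. Cluster correction
thresholds uncorrected p at 0.05, uses the summed F as cluster mass, and
permutes the tested factor's labels at the trial level within subject
(refitting every bin per permutation); corrected significance is mass
above the 95th percentile of the permutation null of maximal masses.
Main effects are the cluster-corrected quantities; interactions are
reported per bin but not cluster-corrected, since permuting a single
factor is not a clean exchangeability scheme for them.

Behavioural models mirror the factorial on the trial table: approach
choice by a logistic model with per-subject intercepts entering as fixed
dummies (the conditional analogue of a random intercept — with ≥ 90
trials per subject the shrinkage difference is negligible, and it
provides the full Wald covariance needed for block F tests), and
approach latency by the random-intercept LME on approach trials only.

## Numerical and design choices

* Probabilities from `decode` are clipped away from {0, 1} by machine
  epsilon only; the ε = 1e−6 logit clip is applied at modelling time.
* Zero-variance trials are skipped in the ACF (logged); an all-degenerate
  series is an error, as are degenerate training base rates
  (p_chance ∈ {0, 1}) and permutation ensembles below 20 members.
* Random seeds flow explicitly through every stochastic step (task,
  recording, baseline draws, CV folds, permutations); identical seeds
  give bit-identical outputs.
* Problem sizes in tests and calibration loops are deliberately
  desk-scale: recovery and power loops use sessions of roughly 40–220
  trials, calibration loops use reduced factorials, ensembles of ≥ 20
  permuted classifiers and 50–120 permutations. Latency-recovery checks
  plant a sharper (25 ms) kernel and use the balanced policy — a
  latency-recovery test wants the peak location, not the class
  imbalance, to limit precision.

## Known limitations

* The renewal model for deliberation-period representation is an
  assumption; real alternation dynamics are unknown and need not be a
  renewal process with independent identities.
* The blink metric and the within-subject permutation scheme for the LME
  cluster test are declared conventions, not unique choices.
* Interactions in the time-course model are not cluster-corrected (see
  above).
* Group-level analyses here treat participants as exchangeable replicas
  of one generator; real between-participant heterogeneity (sensor
  positions, latencies, policies) is not simulated beyond random
  intercepts in the planted effects.
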