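"""Outcome pattern classifiers.

Per-time-bin lasso-regularised logistic regression on sensor patterns,
scored by balanced accuracy (chance 0.5 regardless of class imbalance).
The training objective is

    mean negative log-likelihood + lambda * ||w||_1

with an unpenalised intercept.  The fit is delegated to scikit-learn's
liblinear solver with ``C = 1 / (n * lambda)``; liblinear's intercept
penalty is made negligible via a large ``intercept_scaling`` (the resulting
objective error is of order ``lambda * |intercept| / 1000``, far below the
solver tolerance used in validation).

The module covers the full classifier workflow: cross-validated accuracy
time courses, selection of the group-level peak time bin and of the
participant-specific penalty, the three-contrast classifier suite
(P vs N, P vs baseline, N vs baseline) with 100 permuted-label variants
each, leave-one-condition-out cross-classification, and per-condition
accuracy time courses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .preprocessing import EpochSet

CONTRASTS = ("P_vs_N", "P_vs_base", "N_vs_base")

_INTERCEPT_SCALING = 1000.0


@dataclass
class ClassifierModel:
    """Per-channel weights of one lasso-logistic outcome classifier."""

    weights: np.ndarray
    intercept: float
    lam: float
    train_bin: Optional[int] = None
    contrast: str = "P_vs_N"
    label_permutation_id: Optional[int] = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.weights.size

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Linear score ``X @ w + intercept``."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_channels:
            raise ValueError(
                f"channel mismatch: data has {X.shape[-1]} channels, "
                f"classifier has {self.n_channels}"
            )
        return X @ self.weights + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(positive class) via the standard logistic sigmoid."""
        return 1.0 / (1.0 + np.exp(-self.decision(X)))

    def objective(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean logistic NLL plus the L1 penalty (intercept unpenalised)."""
        z = self.decision(X)
        nll = float(np.mean(np.logaddexp(0.0, z) - np.asarray(y) * z))
        return nll + self.lam * float(np.abs(self.weights).sum())


@dataclass
class AccuracyCurve:
    """Per-time-bin cross-validated balanced accuracy."""

    values: np.ndarray
    lam: float
    n_folds: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("balanced accuracy must lie in [0, 1]")

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.values))


def balanced_accuracy(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Mean of the per-class correct-classification rates.

    ``(TP / all positives + TN / all negatives) / 2`` for binary labels
    coded 0/1.  Undefined (raises) when the truth contains one class only.
    """
    predictions = np.asarray(predictions).astype(int)
    truth = np.asarray(truth).astype(int)
    if predictions.shape != truth.shape or truth.size == 0:
        raise ValueError("predictions and truth must be equal-length, non-empty")
    pos = truth == 1
    neg = truth == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy undefined: truth contains a single class")
    tpr = np.mean(predictions[pos] == 1)
    tnr = np.mean(predictions[neg] == 0)
    return 0.5 * (tpr + tnr)


def train_l1_logistic(X: np.ndarray, y: np.ndarray, lam: float, **model_kw) -> ClassifierModel:
    """Fit one lasso-logistic classifier minimising mean NLL + lam * ||w||_1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError(f"need >= 2 exemplars per class, got {counts.tolist()}")
    n = len(y)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    C = 1.0 / (n * lam)
    # liblinear occasionally stalls at tight tolerance on near-separable
    # bins; retry at a looser (still ample) tolerance before falling back to
    # the much slower saga solver, which is also exact for the unpenalised
    # intercept
    attempts = (
        dict(solver="liblinear", tol=1e-8, max_iter=3000,
             intercept_scaling=_INTERCEPT_SCALING, random_state=0),
        dict(solver="liblinear", tol=1e-6, max_iter=50000,
             intercept_scaling=_INTERCEPT_SCALING, random_state=0),
        dict(solver="saga", tol=1e-7, max_iter=50000, random_state=0),
    )
    clf = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        for kw in attempts:
            candidate = LogisticRegression(l1_ratio=1.0, C=C, **kw)
            try:
                candidate.fit(X, y)
            except UserWarning:
                continue
            clf = candidate
            break
    if clf is None:
        raise RuntimeError(f"L1 logistic fit did not converge at lambda={lam}")
    weights = clf.coef_[0]
    intercept = _polish_intercept(X @ weights, y, float(clf.intercept_[0]))
    return ClassifierModel(weights=weights, intercept=intercept, lam=lam, **model_kw)


def _polish_intercept(z: np.ndarray, y: np.ndarray, b0: float) -> float:
    """Exact unpenalised-intercept MLE given fixed weights (1-D Newton).

    Removes the residual intercept shrinkage left by liblinear's penalised
    intercept parameterisation; for fully penalty-dominated fits (all
    weights zero) this returns the exact base-rate logit.
    """
    ybar = float(np.mean(y))
    b = b0
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(z + b)))
        grad = float(np.mean(p) - ybar)
        hess = float(np.mean(p * (1.0 - p)))
        if hess < 1e-12 or abs(grad) < 1e-12:
            break
        b -= grad / hess
    return b


def _labels_from_meta(epochs: EpochSet, positive: str = "P", negative: str = "N") -> np.ndarray:
    lab = epochs.meta["outcome"].to_numpy()
    keep = np.isin(lab, [positive, negative])
    if not keep.all():
        raise ValueError("epoch set contains outcomes outside the requested contrast")
    return (lab == positive).astype(int)


def _cv_balanced_accuracy(
    X: np.ndarray, y: np.ndarray, lam: float, n_folds: int, seed: int
) -> float:
    """Stratified k-fold CV balanced accuracy, pooled over held-out folds."""
    rare = int(np.bincount(y, minlength=2).min())
    folds = n_folds
    if rare < folds:
        warnings.warn(f"rarer class has {rare} exemplars; reducing folds to {rare}")
        folds = rare
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train, test in skf.split(X, y):
        model = train_l1_logistic(X[train], y[train], lam)
        pred[test] = (model.predict_proba(X[test]) > 0.5).astype(int)
    return balanced_accuracy(pred, y)


def accuracy_timecourse(
    epochs: EpochSet,
    labels: Optional[np.ndarray] = None,
    lam: float = 0.025,
    n_folds: int = 5,
    seed: int = 0,
) -> AccuracyCurve:
    """Cross-validated balanced accuracy at every 10-ms time bin.

    A separate classifier is trained per bin; fold assignment is stratified
    and seeded.  ``labels`` default to outcome == P from the epoch metadata.
    """
    y = _labels_from_meta(epochs) if labels is None else np.asarray(labels).astype(int)
    values = np.array(
        [
            _cv_balanced_accuracy(epochs.at_bin(b), y, lam, n_folds, seed)
            for b in range(epochs.n_bins)
        ]
    )
    return AccuracyCurve(values=values, lam=lam, n_folds=n_folds)


def select_peak_and_lambda(
    curves: Sequence[AccuracyCurve],
    epochs_per_participant: Sequence[EpochSet],
    labels_per_participant: Optional[Sequence[np.ndarray]] = None,
    lambda_grid: Optional[np.ndarray] = None,
    n_folds: int = 5,
    seed: int = 0,
):
    """Group-level peak time bin, then participant-specific penalty.

    The peak bin is the argmax of the mean accuracy curve across
    participants.  At that bin the penalty is optimised per participant by
    cross-validated balanced accuracy over ``lambda_grid`` (default 20
    log-spaced values in [1e-4, 1]); exact ties go to the smaller lambda.
    """
    if not curves:
        raise ValueError("need at least one participant curve")
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 0, 20)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    mean_curve = np.mean([c.values for c in curves], axis=0)
    bin_star = int(np.argmax(mean_curve))

    lam_stars = []
    for i, epochs in enumerate(epochs_per_participant):
        y = (
            _labels_from_meta(epochs)
            if labels_per_participant is None
            else np.asarray(labels_per_participant[i]).astype(int)
        )
        X = epochs.at_bin(bin_star)
        accs = np.array(
            [_cv_balanced_accuracy(X, y, lam, n_folds, seed) for lam in lambda_grid]
        )
        # argmax returns the first maximum; the grid is ascending, so ties
        # resolve to the smaller lambda
        lam_stars.append(float(lambda_grid[int(np.argmax(accs))]))
    return bin_star, lam_stars


def build_classifier_suite(
    epochs: EpochSet,
    baseline: EpochSet,
    bin_star: int,
    lam_star: float,
    seed: int = 0,
    n_permuted: int = 100,
) -> dict:
    """Train the three contrasts at the peak bin plus permuted-label variants.

    Returns ``{contrast: {"model": ClassifierModel, "permuted": [...]}}``.
    P vs N uses outcome epochs at ``bin_star``; the two baseline contrasts
    pit one outcome class against the single-bin baseline exemplars.
    Permuted variants retrain after a seeded random permutation of the
    labels and carry ``label_permutation_id`` 1..n.
    """
    y_outcome = _labels_from_meta(epochs)
    X_outcome = epochs.at_bin(bin_star)
    X_base = baseline.at_bin(0)

    datasets = {"P_vs_N": (X_outcome, y_outcome)}
    for contrast, positive in (("P_vs_base", 1), ("N_vs_base", 0)):
        mask = y_outcome == positive
        if not mask.any():
            raise ValueError(f"no exemplars for the positive class of {contrast}")
        X = np.vstack([X_outcome[mask], X_base])
        y = np.concatenate([np.ones(mask.sum(), int), np.zeros(len(X_base), int)])
        datasets[contrast] = (X, y)

    rng = np.random.default_rng(seed)
    suite = {
        "training_counts": {
            "P": int(y_outcome.sum()),
            "N": int(len(y_outcome) - y_outcome.sum()),
        }
    }
    for contrast, (X, y) in datasets.items():
        model = train_l1_logistic(X, y, lam_star, train_bin=bin_star, contrast=contrast)
        permuted = []
        for pid in range(1, n_permuted + 1):
            yp = rng.permutation(y)
            if yp.min() == yp.max():  # degenerate permutation cannot occur for 2 classes
                continue
            permuted.append(
                train_l1_logistic(
                    X, yp, lam_star, train_bin=bin_star, contrast=contrast,
                    label_permutation_id=pid,
                )
            )
        suite[contrast] = {"model": model, "permuted": permuted}
    return suite


def cross_classification(
    epochs: EpochSet,
    condition: str,
    bin_star: int,
    lam: float,
    labels: Optional[np.ndarray] = None,
) -> dict:
    """Leave-one-condition-level-out classification at the peak bin.

    For each level of ``condition`` ("loss_prob" or "loss_mag") a classifier
    is trained on all other levels and its balanced accuracy measured on the
    held-out level.  Levels whose held-out set lacks a class are skipped with
    a warning and recorded as NaN.
    """
    column = {"loss_prob": "loss_prob_level", "loss_mag": "loss_magnitude"}[condition]
    y = _labels_from_meta(epochs) if labels is None else np.asarray(labels).astype(int)
    X = epochs.at_bin(bin_star)
    values = epochs.meta[column].to_numpy()
    accs = {}
    for level in pd.unique(values):
        held = values == level
        train = ~held
        if len(np.unique(y[train])) < 2 or len(np.unique(y[held])) < 2:
            warnings.warn(f"level {level!r} skipped: a class is missing in train or test")
            accs[level] = np.nan
            continue
        model = train_l1_logistic(X[train], y[train], lam)
        pred = (model.predict_proba(X[held]) > 0.5).astype(int)
        accs[level] = balanced_accuracy(pred, y[held])
    return accs


def wilcoxon_vs_chance(accuracies: np.ndarray, chance: float = 0.5):
    """One-sided Wilcoxon signed-rank test of accuracies above chance."""
    accuracies = np.asarray(accuracies, dtype=float)
    accuracies = accuracies[np.isfinite(accuracies)]
    return wilcoxon(accuracies - chance, alternative="greater")


def per_condition_timecourses(
    epochs: EpochSet,
    bin_star: int,
    lam: float = 0.025,
    n_folds: int = 5,
    seed: int = 0,
    baseline_window_bins: int = 10,
) -> dict:
    """Accuracy time course per loss-probability level, plus baseline-to-peak.

    Baseline-to-peak is the accuracy at ``bin_star`` minus the mean accuracy
    over the first ``baseline_window_bins`` bins (0-100 ms post-outcome).
    Levels lacking negative exemplars are omitted with a warning.
    """
    curves, baseline_to_peak = {}, {}
    for level in ("low", "medium", "high"):
        mask = (epochs.meta["loss_prob_level"] == level).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"loss-probability level {level!r} has no epochs; omitted")
            continue
        y = _labels_from_meta(epochs)[mask]
        if len(np.unique(y)) < 2:
            warnings.warn(f"loss-probability level {level!r} lacks a class; omitted")
            continue
        sub = EpochSet(
            kind=epochs.kind,
            data=epochs.data[mask],
            fs=epochs.fs,
            bin_width_ms=epochs.bin_width_ms,
            window_ms=epochs.window_ms,
            meta=epochs.meta.loc[mask].reset_index(drop=True),
            channels=epochs.channels,
        )
        curve = accuracy_timecourse(sub, lam=lam, n_folds=n_folds, seed=seed)
        curves[level] = curve
        baseline_to_peak[level] = float(
            curve.values[bin_star] - curve.values[:baseline_window_bins].mean()
        )
    return {"curves": curves, "baseline_to_peak": baseline_to_peak}
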