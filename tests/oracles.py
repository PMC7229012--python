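"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation paths they check.
"""

import itertools

import numpy as np


def catch_probability_enumeration(per_bin_prob: float, n_bins: int) -> float:
    """Catch probability by exhaustive enumeration of all bin outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=n_bins):
        p = 1.0
        for o in outcome:
            p *= per_bin_prob if o else 1.0 - per_bin_prob
        if any(outcome):
            total += p
    return total


def balanced_accuracy_counting(pred, truth) -> float:
    """Balanced accuracy by explicit counting over the confusion table."""
    tp = fn = tn = fp = 0
    for p, t in zip(pred, truth):
        if t == 1:
            tp, fn = (tp + 1, fn) if p == 1 else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p == 0 else (tn, fp + 1)
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def l1_logistic_objective(w, b, X, y, lam) -> float:
    z = X @ np.asarray(w) + b
    nll = np.mean(np.logaddexp(0.0, z) - y * z)
    return float(nll + lam * np.abs(w).sum())


def l1_logistic_grid_search(X, y, lam, span=4.0, points=13, zooms=6):
    """Iteratively-refined grid search over (weights, intercept).

    Coarse-to-fine search of the full objective on a regular grid per
    coordinate axis (all combinations), recentred and shrunk at each zoom.
    Exponential in the number of features, so only usable on tiny problems.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    d = X.shape[1]
    center = np.zeros(d + 1)
    width = span
    best = None
    for _ in range(zooms):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([g.ravel() for g in grids], axis=1)  # (m, d+1)
        z = X @ cand[:, :d].T + cand[:, d]
        nll = np.mean(np.logaddexp(0.0, z) - y[:, None] * z, axis=0)
        obj = nll + lam * np.abs(cand[:, :d]).sum(axis=1)
        k = int(np.argmin(obj))
        center = cand[k]
        best = float(obj[k])
        width = width * 2.0 / (points - 1) * 1.5  # keep neighbouring cells covered
    return center[:d], center[d], best
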