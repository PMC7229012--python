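"""Mixed-model inference on decoded probabilities and behaviour.

Decoded representation probabilities are transformed with an inverse
sigmoid (logit, boundary-clipped) and modelled per time bin with a linear
mixed model: full-factorial fixed effects of loss probability (3 levels),
loss magnitude (6 levels) and choice (2 levels), all coded categorically
with treatment contrasts, plus a random per-subject intercept.  F-tests per
fixed-effect term use Wald block statistics with a conservative denominator
degrees of freedom df = N - K, where N is the number of observations and K
the count of all fixed and random effects.  Multiple-comparison correction
across time bins is a cluster-level permutation test (inclusion threshold
p < 0.05, cluster mass = sum of F values, labels of the tested factor
permuted at the trial level within subject).

The random-intercept model is fitted by profiled REML: for a given
variance ratio rho = sigma_b^2 / sigma^2 the GLS solution reduces to OLS on
within-group shrinkage-transformed data, leaving a one-dimensional REML
criterion that is minimised numerically.  statsmodels' MixedLM serves as an
independent cross-check in the test suite.

Behavioural models mirror the same factorial structure on the trial table:
a logistic model for the approach choice (per-subject intercepts entering
as fixed dummies, the conditional analogue of the random intercept) and a
linear mixed model for approach latency on approach trials only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_EPS = 1e-6

FACTORS = ("loss_prob_level", "loss_magnitude", "choice")


def sigmoid(x):
    """Standard logistic function 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def inverse_sigmoid(p, eps: float = DEFAULT_EPS):
    """Logit transform with boundary clipping.

    ``Y = ln(p' / (1 - p'))`` with ``p' = clip(p, eps, 1 - eps)``, so the
    transform is finite on the closed interval [0, 1].
    """
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# design matrices


def _dummy_block(values: np.ndarray, levels: Sequence) -> np.ndarray:
    """Treatment-coded dummies for all non-reference levels (first = ref)."""
    return np.column_stack([(values == lv).astype(float) for lv in levels[1:]])


def build_design(df: pd.DataFrame, factors: Sequence[str]):
    """Full-factorial treatment-coded design matrix with term bookkeeping.

    Returns ``(X, terms)`` where ``X`` includes an intercept column and
    ``terms`` maps each term name ("A", "A:B", ...) to its column indices.
    Reference levels are the lexicographically first level of each factor.
    """
    blocks = {}
    for f in factors:
        levels = sorted(pd.unique(df[f]), key=str)
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        blocks[f] = _dummy_block(df[f].to_numpy(), levels)

    columns = [np.ones((len(df), 1))]
    terms = {}
    start = 1
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            name = ":".join(combo)
            block = blocks[combo[0]]
            for f in combo[1:]:
                # interaction columns: all pairwise products of dummy columns
                block = np.einsum("ni,nj->nij", block, blocks[f]).reshape(len(df), -1)
            columns.append(block)
            terms[name] = np.arange(start, start + block.shape[1])
            start += block.shape[1]
    return np.hstack(columns), terms


# ---------------------------------------------------------------------------
# random-intercept LME by profiled REML


@dataclass
class RandomInterceptFit:
    """Fitted random-intercept linear mixed model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    sigma_b2: float
    n_obs: int
    n_groups: int
    n_fixed: int
    reml_criterion: float

    @property
    def df_denominator(self) -> int:
        """Conservative residual df: N minus all fixed and random effects."""
        return self.n_obs - self.n_fixed - self.n_groups


def _shrink_transform(y, X, counts, starts, inv, rho):
    """Apply the within-group GLS shrinkage transform for variance ratio rho.

    Rows are assumed sorted by group; ``starts`` are the group start
    offsets and ``inv`` maps each row to its group index.
    """
    alpha = 1.0 - np.sqrt(1.0 / (1.0 + counts * rho))
    y_mean = np.add.reduceat(y, starts) / counts
    X_mean = np.add.reduceat(X, starts, axis=0) / counts[:, None]
    yt = y - alpha[inv] * y_mean[inv]
    Xt = X - alpha[inv, None] * X_mean[inv]
    return yt, Xt


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool = True
) -> RandomInterceptFit:
    """REML fit of ``y = X beta + Z b + eps`` with a random intercept per group.

    Data are internally sorted by group; the variance ratio is profiled out
    and optimised on a log scale with a bounded scalar search.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    uniq, inv_unsorted, counts = np.unique(groups, return_inverse=True, return_counts=True)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    inv = inv_unsorted  # rows already sorted by group
    n, p = X.shape
    q = len(uniq)

    BAD = 1e300  # finite sentinel: keeps the bounded search warning-free

    def criterion(log_rho):
        rho = np.exp(log_rho)
        yt, Xt = _shrink_transform(y, X, counts, starts, inv, rho)
        G = Xt.T @ Xt
        try:
            beta = np.linalg.solve(G, Xt.T @ yt)
        except np.linalg.LinAlgError:
            return BAD
        rss = float(yt @ yt - beta @ (Xt.T @ yt))
        if rss <= 0:
            return BAD
        logdet_v = float(np.sum(np.log1p(counts * rho)))
        if reml:
            sign, logdet_g = np.linalg.slogdet(G)
            if sign <= 0:
                return BAD
            return (n - p) * np.log(rss) + logdet_v + logdet_g
        return n * np.log(rss) + logdet_v

    res = optimize.minimize_scalar(criterion, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    candidates = [(criterion(res.x), np.exp(res.x)), (criterion(-30.0), 0.0)]
    _, rho = min(candidates, key=lambda c: c[0])

    yt, Xt = _shrink_transform(y, X, counts, starts, inv, rho)
    G = Xt.T @ Xt
    beta = np.linalg.solve(G, Xt.T @ yt)
    rss = float(yt @ yt - beta @ (Xt.T @ yt))
    dof = (n - p) if reml else n
    sigma2 = rss / dof
    cov_beta = sigma2 * np.linalg.inv(G)
    crit = criterion(np.log(rho) if rho > 0 else -30.0)
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        sigma_b2=rho * sigma2,
        n_obs=n,
        n_groups=q,
        n_fixed=p,
        reml_criterion=float(crit),
    )


def wald_f_test(fit: RandomInterceptFit, columns: np.ndarray):
    """Wald block F-test of a set of fixed-effect coefficients being zero."""
    b = fit.beta[columns]
    V = fit.cov_beta[np.ix_(columns, columns)]
    q = len(columns)
    F = float(b @ np.linalg.solve(V, b)) / q
    df_den = fit.df_denominator
    if df_den <= 0:
        raise ValueError("non-positive denominator degrees of freedom")
    p = float(stats.f.sf(F, q, df_den))
    return F, p, q, df_den


# ---------------------------------------------------------------------------
# time-course models


@dataclass
class LmeTimecourseResult:
    """Per-bin F statistics and p-values for each fixed-effect term."""

    bins: np.ndarray
    f_values: dict  # term -> array over bins
    p_values: dict  # term -> array over bins
    term_df: dict  # term -> numerator df
    df_denominator: int
    flagged_bins: list


def series_to_long(series_list) -> pd.DataFrame:
    """Stack per-participant ProbSeries into a long trial x bin table."""
    frames = []
    for s in series_list:
        n_t, n_b = s.values.shape
        meta = s.meta.reset_index(drop=True)
        df = pd.DataFrame(
            {
                "subject": np.repeat(meta["participant_id"].to_numpy(), n_b),
                "trial_id": np.repeat(meta["trial_id"].to_numpy(), n_b),
                "bin": np.tile(np.arange(n_b), n_t),
                "p": s.values.ravel(),
                "loss_prob_level": np.repeat(meta["loss_prob_level"].to_numpy(), n_b),
                "loss_magnitude": np.repeat(meta["loss_magnitude"].to_numpy(), n_b),
                "choice": np.repeat(meta["choice"].to_numpy(), n_b),
            }
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _pivot_long(long_df: pd.DataFrame, factors: Sequence[str]):
    """Split a long table into per-trial metadata and a trials x bins matrix."""
    key = ["subject", "trial_id"]
    wide = long_df.pivot_table(index=key, columns="bin", values="p", sort=True)
    trial_meta = (
        long_df.drop_duplicates(key).set_index(key).loc[wide.index].reset_index()
    )
    return trial_meta, wide.to_numpy()


def fit_lme_timecourse(
    long_df: pd.DataFrame,
    factors: Sequence[str] = FACTORS,
    eps: float = DEFAULT_EPS,
) -> LmeTimecourseResult:
    """Fit the per-bin random-intercept LME and extract fixed-effect F tests.

    ``long_df`` is a long table with columns subject, trial_id, bin, p and
    the factor columns.  Each bin's probabilities are logit-transformed and
    modelled with the full factorial of ``factors`` plus a random subject
    intercept.  Singular bins are flagged and carry NaN statistics.
    """
    factors = [f for f in factors if long_df[f].nunique() > 1]
    if long_df["subject"].nunique() < 2:
        raise ValueError("need at least two subjects")
    trial_meta, Y = _pivot_long(long_df, factors)
    X, terms = build_design(trial_meta, factors)
    groups = trial_meta["subject"].to_numpy()
    n_bins = Y.shape[1]

    f_values = {t: np.full(n_bins, np.nan) for t in terms}
    p_values = {t: np.full(n_bins, np.nan) for t in terms}
    flagged = []
    df_den = None
    for b in range(n_bins):
        y = inverse_sigmoid(Y[:, b], eps)
        try:
            fit = fit_random_intercept(y, X, groups)
            for t, cols in terms.items():
                F, p, q, df_den = wald_f_test(fit, cols)
                f_values[t][b] = F
                p_values[t][b] = p
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"bin {b} flagged as singular: {exc}")
            flagged.append(b)
    if df_den is None:
        raise ValueError("no bin could be fitted")
    return LmeTimecourseResult(
        bins=np.arange(n_bins),
        f_values=f_values,
        p_values=p_values,
        term_df={t: len(cols) for t, cols in terms.items()},
        df_denominator=df_den,
        flagged_bins=flagged,
    )


def _clusters_from_pvalues(p: np.ndarray, f: np.ndarray, alpha: float):
    """Maximal runs of uncorrected p < alpha; mass = sum of F values."""
    above = np.nan_to_num(p, nan=1.0) < alpha
    clusters = []
    i, n = 0, len(p)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            clusters.append(dict(start=i, end=j, mass=float(np.nansum(f[i:j]))))
            i = j
        else:
            i += 1
    return clusters


def _permute_within_subject(trial_meta: pd.DataFrame, column: str, rng) -> np.ndarray:
    values = trial_meta[column].to_numpy().copy()
    for s in pd.unique(trial_meta["subject"]):
        idx = np.flatnonzero(trial_meta["subject"].to_numpy() == s)
        values[idx] = values[idx[rng.permutation(len(idx))]]
    return values


def cluster_correct_timecourse(
    long_df: pd.DataFrame,
    effects: Sequence[str] = ("loss_prob_level", "loss_magnitude", "choice"),
    factors: Sequence[str] = FACTORS,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    eps: float = DEFAULT_EPS,
) -> dict:
    """Cluster-level permutation correction of the LME time course.

    For each tested main effect, clusters are maximal runs of bins with
    uncorrected p < ``alpha`` and mass the sum of F values.  The null
    distribution of maximal cluster masses is built by permuting that
    factor's labels at the trial level within subject and refitting every
    bin; a cluster is significant when its mass exceeds the null's 95th
    percentile.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    factors = [f for f in factors if long_df[f].nunique() > 1]
    trial_meta, Y = _pivot_long(long_df, factors)
    X, terms = build_design(trial_meta, factors)
    groups = trial_meta["subject"].to_numpy()
    n_bins = Y.shape[1]
    Ylogit = inverse_sigmoid(Y, eps)

    def f_and_p(design, term_cols):
        F = np.full(n_bins, np.nan)
        P = np.full(n_bins, np.nan)
        for b in range(n_bins):
            try:
                fit = fit_random_intercept(Ylogit[:, b], design, groups)
                F[b], P[b], _, _ = wald_f_test(fit, term_cols)
            except (np.linalg.LinAlgError, ValueError):
                pass
        return F, P

    rng = np.random.default_rng(seed)
    out = {}
    for effect in effects:
        if effect not in terms:
            continue
        cols = terms[effect]
        F_obs, P_obs = f_and_p(X, cols)
        clusters = _clusters_from_pvalues(P_obs, F_obs, alpha)
        null_max = np.zeros(n_perm)
        for k in range(n_perm):
            meta_perm = trial_meta.copy()
            meta_perm[effect] = _permute_within_subject(trial_meta, effect, rng)
            X_perm, terms_perm = build_design(meta_perm, factors)
            F_p, P_p = f_and_p(X_perm, terms_perm[effect])
            cl = _clusters_from_pvalues(P_p, F_p, alpha)
            null_max[k] = max((c["mass"] for c in cl), default=0.0)
        thr = float(np.percentile(null_max, 95))
        for c in clusters:
            c["significant"] = c["mass"] > thr
            c["p_corrected"] = float((null_max >= c["mass"]).mean())
        out[effect] = dict(
            f_values=F_obs, p_values=P_obs, clusters=clusters,
            null_max_masses=null_max, threshold=thr,
        )
    return out


# ---------------------------------------------------------------------------
# behavioural models


def behaviour_lme(trials: pd.DataFrame) -> dict:
    """Condition effects on approach choice and approach latency.

    ``trials`` must span several subjects (column ``subject``) and contain
    the non-training trials.  The approach model is logistic in the loss
    probability x loss magnitude factorial with per-subject intercepts; the
    latency model is the random-intercept LME on approach trials only.
    Returns per-term F statistics with df = N - K.
    """
    import statsmodels.api as sm

    main = trials.loc[~trials["is_training"]].reset_index(drop=True)
    y = (main["choice"] == "approach").to_numpy(float)
    if y.min() == y.max():
        raise ValueError("approach model needs both choices present in the data")
    factors = ["loss_prob_level", "loss_magnitude"]
    X, terms = build_design(main, factors)
    subjects = sorted(main["subject"].unique())
    # per-subject intercepts replace the global intercept column
    S = np.column_stack([(main["subject"] == s).astype(float) for s in subjects])
    Xs = np.hstack([X[:, 1:], S])
    fit = sm.Logit(y, Xs).fit(disp=0, maxiter=200)
    cov = np.asarray(fit.cov_params())
    K = Xs.shape[1]
    df_den = len(y) - K
    approach = {}
    for t, cols in terms.items():
        cols0 = cols - 1  # intercept column dropped
        b = fit.params[cols0]
        V = cov[np.ix_(cols0, cols0)]
        q = len(cols0)
        F = float(b @ np.linalg.solve(V, b)) / q
        approach[t] = dict(F=F, p=float(stats.f.sf(F, q, df_den)), df=(q, df_den))

    appr = main.loc[main["choice"] == "approach"].reset_index(drop=True)
    Xl, terms_l = build_design(appr, factors)
    lat_fit = fit_random_intercept(
        appr["action_latency"].to_numpy(float), Xl, appr["subject"].to_numpy()
    )
    latency = {}
    for t, cols in terms_l.items():
        F, p, q, dfd = wald_f_test(lat_fit, cols)
        latency[t] = dict(F=F, p=p, df=(q, dfd))
    return dict(
        approach=approach,
        latency=latency,
        n_obs_approach_model=len(y),
        n_obs_latency_model=len(appr),
    )
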