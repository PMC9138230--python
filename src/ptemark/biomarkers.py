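"""Combinatory-biomarker evaluation by cross-validated pooled-AUC ROC.

A feature panel (e.g. PTZ-test parameters A-E, sleep parameters F-M) is
scored by ridge-stabilized logistic regression against a binary group
contrast. Overfitting is assessed by leave-one-out cross-validation: the
model is refitted n times, each time predicting the held-out animal, and a
single ROC is built from the pooled held-out probabilities (the "pooling
method" — with folds of size one there is no per-fold ROC to average). The
95% CI of the cross-validated AUC comes from a bias-corrected and
accelerated (BCa) bootstrap over the pooled (score, label) pairs.

The pooled leave-one-out AUC is a pessimistically biased estimator: held-out
predictions are mildly anti-correlated with the training fit, so
uninformative panels score below 0.5 rather than at it (see
docs/methods.md). Apparent (resubstitution) AUC is reported alongside.

Features are z-scored inside each training fold (fold statistics only, no
leakage); the slope penalty guarantees a finite fit under perfect
separation, the intercept is never penalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "FeaturePanel",
    "BiomarkerEvaluation",
    "roc_auc",
    "fit_logistic",
    "loo_pooled_scores",
    "cross_validated_auc",
    "bca_ci",
    "confusion_metrics",
    "evaluate_panel",
]

DEFAULT_RIDGE = 1e-6
DEFAULT_B = 2000
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = (#{pos > neg} + 0.5 #{ties}) / (n_pos * n_neg).

    Computed via midranks (the Mann-Whitney U statistic with tie
    correction), which equals the trapezoidal area under the empirical ROC.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = sps.rankdata(s)
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Logistic scoring
# ---------------------------------------------------------------------------

def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Maximum-penalized-likelihood logistic coefficients [b0, b1..bp].

    Penalty ridge/2 * ||slopes||^2 on slopes only; the intercept is free.
    Newton iterations with step halving; raises on non-convergence.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (animals x features)")
    n, p = X.shape
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes 0 and 1")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    Xd = np.column_stack([np.ones(n), X])
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    w = np.zeros(p + 1)

    def negloglik(w):
        eta = Xd @ w
        # log(1 + exp(eta)) - y*eta, numerically stable
        return float(
            np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(pen * w**2)
        )

    f = negloglik(w)
    for _ in range(max_iter):
        eta = Xd @ w
        mu = sps.logistic.cdf(eta)
        grad = Xd.T @ (mu - y) + pen * w
        wdiag = np.clip(mu * (1 - mu), 1e-12, None)
        H = (Xd * wdiag[:, None]).T @ Xd + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the penalized deviance non-increasing
        t = 1.0
        for _ in range(40):
            w_new = w - t * step
            f_new = negloglik(w_new)
            if f_new <= f + 1e-12:
                break
            t /= 2.0
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w, f = w_new, f_new
    if np.max(np.abs(step)) < 1e-6:
        return w
    raise RuntimeError(
        f"logistic fit did not converge in {max_iter} iterations "
        f"(n={n}, p={p}, ridge={ridge}, |step|={np.max(np.abs(step)):.3g})"
    )


def predict_proba(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    return sps.logistic.cdf(w[0] + X @ w[1:])


def _fold_standardize(Xtr: np.ndarray, Xte: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def loo_pooled_scores(
    X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> np.ndarray:
    """Held-out probability for each animal under leave-one-out refitting.

    Standardization parameters are recomputed inside each training fold.
    A fold whose training set loses one class entirely yields NaN for that
    animal (reported, not silently dropped).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n = len(y)
    if n < 4:
        raise ValueError("leave-one-out needs n >= 4")
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        ytr = y[mask]
        if len(np.unique(ytr)) < 2:
            out[i] = np.nan
            continue
        Xtr, Xte = _fold_standardize(X[mask], X[i : i + 1])
        w = fit_logistic(Xtr, ytr, ridge=ridge)
        out[i] = predict_proba(w, Xte)[0]
    return out


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def bca_ci(
    stat: Callable[[np.ndarray], float],
    data: np.ndarray,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = 0,
    valid: Optional[Callable[[np.ndarray], bool]] = None,
    max_redraw: int = 100,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for ``stat(data)``.

    ``data`` is resampled by rows. z0 is the normal quantile of the fraction
    of bootstrap replicates below the point estimate; the acceleration a
    comes from the jackknife skewness of the statistic. Degenerate resamples
    (``valid`` returns False, e.g. one-class label resamples) are redrawn;
    if every replicate equals the point estimate the interval collapses to
    the point.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.asarray(data)
    n = data.shape[0]
    theta = stat(data)

    boot = np.empty(B)
    for b in range(B):
        for _ in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            sample = data[idx]
            if valid is None or valid(sample):
                break
        else:
            raise RuntimeError("could not draw a valid bootstrap resample")
        boot[b] = stat(sample)

    if np.all(boot == theta):
        return (theta, theta)

    # bias correction: fraction of replicates strictly below the estimate,
    # half weight on ties, clipped away from 0/1
    prop = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / B
    prop = min(max(prop, 1.0 / (2 * B)), 1 - 1.0 / (2 * B))
    z0 = sps.norm.ppf(prop)

    # acceleration from jackknife skewness
    jack = np.empty(n)
    for i in range(n):
        jack[i] = stat(np.delete(data, i, axis=0))
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = 0.0 if den == 0 else num / den

    def endpoint(q: float) -> float:
        z = sps.norm.ppf(q)
        adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        return float(np.quantile(boot, adj))

    return endpoint(alpha / 2), endpoint(1 - alpha / 2)


def cross_validated_auc(
    X: np.ndarray,
    y: np.ndarray,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = 0,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[float, tuple[float, float]]:
    """Pooled leave-one-out AUC with a BCa bootstrap 95% CI, clipped to [0,1].

    The bootstrap resamples the pooled (held-out score, label) pairs rather
    than re-running the cross-validation inside each replicate — an
    approximation that keeps B = 2000 affordable and matches the common
    AUC-CI toolchain.
    """
    scores = loo_pooled_scores(X, y, ridge=ridge)
    ok = ~np.isnan(scores)
    y = np.asarray(y, int)
    pairs = np.column_stack([scores[ok], y[ok].astype(float)])
    cv_auc = roc_auc(pairs[:, 0], pairs[:, 1].astype(int))

    def stat(d: np.ndarray) -> float:
        return roc_auc(d[:, 0], d[:, 1].astype(int))

    def valid(d: np.ndarray) -> bool:
        lab = d[:, 1]
        return lab.min() == 0 and lab.max() == 1

    lo, hi = bca_ci(stat, pairs, B=B, alpha=alpha, seed=seed, valid=valid)
    return cv_auc, (max(0.0, lo), min(1.0, hi))


# ---------------------------------------------------------------------------
# Confusion metrics and panel assembly
# ---------------------------------------------------------------------------

def confusion_metrics(
    pooled_scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> tuple[float, float, float, Optional[float]]:
    """(misclassification, sensitivity, specificity, precision) at threshold.

    A score >= threshold predicts positive. Precision is None when nothing
    is predicted positive.
    """
    s = np.asarray(pooled_scores, float)
    y = np.asarray(labels, int)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    mis = (fp + fn) / len(y)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    return mis, sens, spec, prec


@dataclass(frozen=True)
class FeaturePanel:
    """A named feature matrix with binary contrast labels.

    Rows with any missing feature are removed (listwise deletion) at
    construction; both classes must retain at least two animals.
    """

    feature_names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    contrast_name: str
    animal_ids: tuple[str, ...] = ()

    @staticmethod
    def from_frame(df, feature_names, label_col, contrast_name=""):
        import pandas as pd

        missing = [f for f in feature_names if f not in df.columns]
        if missing:
            raise KeyError(f"panel features absent from cohort table: {missing}")
        sub = df[list(feature_names) + [label_col]].copy()
        ids = df["animal_id"].astype(str) if "animal_id" in df.columns else sub.index.astype(str)
        keep = ~sub.isna().any(axis=1)
        dropped = list(ids[~keep])
        sub = sub[keep]
        y = sub[label_col].astype(int).to_numpy()
        for cls in (0, 1):
            if int((y == cls).sum()) < 2:
                raise ValueError(
                    f"fewer than 2 animals in class {cls} after listwise deletion "
                    f"(dropped: {dropped})"
                )
        return FeaturePanel(
            feature_names=tuple(feature_names),
            X=sub[list(feature_names)].to_numpy(float),
            y=y,
            contrast_name=contrast_name or label_col,
            animal_ids=tuple(ids[keep]),
        )


@dataclass(frozen=True)
class BiomarkerEvaluation:
    contrast_name: str
    feature_names: tuple[str, ...]
    apparent_auc: float
    cv_auc: float
    cv_ci: tuple[float, float]
    misclassification_rate: float
    sensitivity: float
    specificity: float
    precision: Optional[float]
    n_pos: int
    n_neg: int
    seed: int


def evaluate_panel(
    panel: FeaturePanel,
    seed: int = 0,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = 0.5,
) -> BiomarkerEvaluation:
    """Full evaluation of one panel; deterministic given the seed.

    Apparent AUC comes from refitting and scoring on all animals; the
    cross-validated AUC, its BCa CI, and the confusion metrics come from the
    pooled held-out leave-one-out probabilities.
    """
    X, y = panel.X, panel.y
    Xz, _ = _fold_standardize(X, X)
    w = fit_logistic(Xz, y, ridge=ridge)
    apparent = roc_auc(predict_proba(w, Xz), y)

    scores = loo_pooled_scores(X, y, ridge=ridge)
    ok = ~np.isnan(scores)
    cv_auc = roc_auc(scores[ok], y[ok])

    pairs = np.column_stack([scores[ok], y[ok].astype(float)])

    def stat(d):
        return roc_auc(d[:, 0], d[:, 1].astype(int))

    def valid(d):
        return d[:, 1].min() == 0 and d[:, 1].max() == 1

    lo, hi = bca_ci(stat, pairs, B=B, alpha=alpha,
                    seed=np.random.default_rng(seed), valid=valid)
    mis, sens, spec, prec = confusion_metrics(scores, y, threshold=threshold)
    return BiomarkerEvaluation(
        contrast_name=panel.contrast_name,
        feature_names=panel.feature_names,
        apparent_auc=apparent,
        cv_auc=cv_auc,
        cv_ci=(max(0.0, lo), min(1.0, hi)),
        misclassification_rate=mis,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        seed=seed,
    )
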