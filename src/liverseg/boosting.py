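"""Discrete AdaBoost with decision stumps, and the margin-to-probability map.

The classifier margin ``H(f) = sum_m alpha_m * h_m(f)`` (weak votes
``h_m in {-1, +1}``) is converted to a liver probability by the logistic
transform ``p = e^H / (e^H + e^{-H})``.  The margin is deliberately left
unnormalized: confidently classified pixels then saturate towards
probability 0 or 1, which is what makes automatic seed selection for the
random walker possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

_ERR_CLAMP = 1e-10


@dataclass(frozen=True)
class Stump:
    """Depth-1 weak learner: vote +1 when ``polarity*(x[feature] - threshold) > 0``."""

    feature: int
    threshold: float
    polarity: int  # +1 or -1

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Votes in {-1, +1} for rows of X."""
        s = self.polarity * (X[:, self.feature] - self.threshold)
        return np.where(s > 0, 1, -1)


@dataclass(frozen=True)
class BoostedClassifier:
    stumps: tuple[Stump, ...]
    weights: tuple[float, ...]  # alpha_m
    n_features: int

    def __post_init__(self) -> None:
        if len(self.stumps) != len(self.weights):
            raise ValueError("one weight per stump required")

    def margin(self, X: np.ndarray) -> np.ndarray:
        """H(f) for each row of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) feature matrix, got {X.shape}"
            )
        H = np.zeros(X.shape[0])
        for stump, alpha in zip(self.stumps, self.weights):
            H += alpha * stump.predict(X)
        return H

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return margin_to_prob(self.margin(X))


def margin_to_prob(H):
    """Liver probability ``e^H / (e^H + e^{-H})``, overflow-safe.

    Equals the logistic sigmoid of 2H; strictly increasing, with
    ``margin_to_prob(-H) == 1 - margin_to_prob(H)``.
    """
    return expit(2.0 * np.asarray(H, dtype=float))


def _best_stump(X: np.ndarray, y_pm: np.ndarray, w: np.ndarray, order: np.ndarray):
    """Exhaustive weighted stump search.

    For every feature, thresholds at midpoints between consecutive sorted
    values are scored with cumulative sums; ties break on (error, feature
    index, threshold) so training is deterministic.

    Returns (feature, threshold, polarity, weighted_error).
    """
    n, F = X.shape
    best = (np.inf, 0, -np.inf, 1)  # err, feature, threshold, polarity
    for f in range(F):
        idx = order[:, f]
        xv = X[idx, f]
        wy = (w * y_pm)[idx]
        # stump "predict +1 for x > t": err(t) = sum_{x<=t, y=+1} w + sum_{x>t, y=-1} w
        csum = np.cumsum(wy)  # sum of w*y for the k smallest values
        total_neg = w[y_pm < 0].sum()
        # cut after position k (threshold between xv[k-1] and xv[k]):
        # err_plus(k) = total_neg + sum_{i<k} w_i y_i
        err_plus = total_neg + np.concatenate(([0.0], csum))
        err_minus = 1.0 - err_plus  # weights sum to 1
        # valid cuts: k where xv[k-1] < xv[k], plus the two trivial ends
        valid = np.concatenate(([True], xv[1:] > xv[:-1], [True]))
        thresholds = np.concatenate(([xv[0] - 1.0], 0.5 * (xv[1:] + xv[:-1]), [xv[-1] + 1.0]))
        for errs, pol in ((err_plus, 1), (err_minus, -1)):
            e = np.where(valid, errs, np.inf)
            k = int(np.argmin(e))
            if e[k] < best[0] - 1e-15:
                best = (float(e[k]), f, float(thresholds[k]), pol)
    err, f, t, pol = best
    return f, t, pol, err


def train_boost(X: np.ndarray, y: np.ndarray, n_rounds: int = 100, rng_seed: int = 0) -> BoostedClassifier:
    """Train discrete AdaBoost with depth-1 stumps.

    Parameters
    ----------
    X : (n, F) feature matrix;  y : (n,) labels in {0, 1}.
    n_rounds : maximum number of boosting rounds (stops early once the
        training error hits zero).
    rng_seed : accepted for interface uniformity; training itself is
        deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, F) with one label per row")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"both classes {{0,1}} required, got labels {classes}")

    y_pm = np.where(y == 1, 1.0, -1.0)
    n = X.shape[0]
    w = np.full(n, 1.0 / n)
    order = np.argsort(X, axis=0, kind="stable")

    stumps: list[Stump] = []
    alphas: list[float] = []
    for _ in range(n_rounds):
        f, t, pol, err = _best_stump(X, y_pm, w, order)
        err = min(max(err, _ERR_CLAMP), 1.0 - _ERR_CLAMP)
        alpha = 0.5 * np.log((1.0 - err) / err)
        stump = Stump(feature=f, threshold=t, polarity=pol)
        stumps.append(stump)
        alphas.append(float(alpha))
        pred = stump.predict(X)
        if err <= _ERR_CLAMP:  # perfectly separated: further rounds are redundant
            break
        w = w * np.exp(-alpha * y_pm * pred)
        w /= w.sum()
    return BoostedClassifier(stumps=tuple(stumps), weights=tuple(alphas), n_features=X.shape[1])
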