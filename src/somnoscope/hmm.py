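"""Unsupervised two-state (sleep/wake) Gaussian hidden Markov model.

One HMM is fitted per subject to the full concatenated minute series of
log(1+MIMS) activity, by Baum-Welch EM with scaled forward-backward
recursions (stable for week-long series, T ≈ 10080).  The state with the
smaller emission mean is sleep; minutes are labelled by posterior (local)
decoding — sleep iff the smoothed P(sleep) exceeds 0.5, ties to wake —
with Viterbi decoding available as an alternative.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``score``, fitted attributes with trailing
underscores) and a functional surface (:func:`fit_em`, :func:`decode`,
:func:`forward_loglik`) wraps it.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

_PDF_FLOOR = 1e-300
_SD_FLOOR = 1e-2


def transform_counts(x) -> np.ndarray:
    """y = log(1 + x): monotone, 0 -> 0.  Rejects negatives (sentinels
    must have been masked upstream)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite activity values")
    if (x < 0).any():
        raise ValueError("negative activity values; mask sentinels first")
    return np.log1p(x)


def _emission_probs(y, means, sds):
    b = norm.pdf(y[:, None], loc=means[None, :], scale=sds[None, :])
    return np.maximum(b, _PDF_FLOOR)


@njit(cache=True)
def _forward_backward(pi, A, B):
    """Scaled forward-backward.  Returns (loglik, gamma, xi_sum)."""
    T, S = B.shape
    alpha = np.empty((T, S))
    beta = np.empty((T, S))
    c = np.empty(T)

    for s in range(S):
        alpha[0, s] = pi[s] * B[0, s]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = acc * B[t, j]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(S):
            acc = 0.0
            for j in range(S):
                acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]

    gamma = alpha * beta
    for t in range(T):
        tot = gamma[t].sum()
        gamma[t] /= tot

    xi_sum = np.zeros((S, S))
    for t in range(T - 1):
        for i in range(S):
            for j in range(S):
                xi_sum[i, j] += (alpha[t, i] * A[i, j] * B[t + 1, j]
                                 * beta[t + 1, j] / c[t + 1])

    return np.log(c).sum(), gamma, xi_sum


@njit(cache=True)
def _viterbi(log_pi, log_A, log_B):
    T, S = log_B.shape
    delta = np.empty((T, S))
    back = np.zeros((T, S), dtype=np.int64)
    delta[0] = log_pi + log_B[0]
    for t in range(1, T):
        for j in range(S):
            best, arg = -1e308, 0
            for i in range(S):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:
                    best, arg = v, i
            delta[t, j] = best + log_B[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta[T - 1])
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def forward_loglik(pi, A, means, sds, y) -> float:
    """Exact marginal log-likelihood via the scaled forward recursion."""
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite series")
    B = _emission_probs(y, np.asarray(means, float), np.asarray(sds, float))
    ll, _, _ = _forward_backward(np.asarray(pi, float),
                                 np.asarray(A, float), B)
    return float(ll)


def brute_force_loglik(pi, A, means, sds, y, max_T: int = 16) -> float:
    """Log-likelihood by explicit enumeration of all 2^T state paths.

    Test oracle only; refuses T > ``max_T``.
    """
    y = np.asarray(y, float)
    T = len(y)
    if T > max_T:
        raise ValueError(f"brute force limited to T <= {max_T}")
    pi, A = np.asarray(pi, float), np.asarray(A, float)
    means, sds = np.asarray(means, float), np.asarray(sds, float)
    S = len(pi)
    log_pi = np.log(np.maximum(pi, 1e-300))
    log_A = np.log(np.maximum(A, 1e-300))
    log_B = norm.logpdf(y[:, None], means[None, :], sds[None, :])
    paths = np.array(list(itertools.product(range(S), repeat=T)))
    lp = log_pi[paths[:, 0]] + log_B[0, paths[:, 0]]
    for t in range(1, T):
        lp += log_A[paths[:, t - 1], paths[:, t]] + log_B[t, paths[:, t]]
    return float(logsumexp(lp))


class DegenerateSeriesError(ValueError):
    """Raised when decoding is requested on a degenerate (constant) fit."""


class SleepWakeHMM(BaseEstimator):
    """Two-state Gaussian HMM on log(1+activity), fitted by Baum-Welch.

    Parameters
    ----------
    init : {"quantile_split", "kmeans"}
        Initial emission means at the 25th/75th percentile of the series
        (deterministic default) or from a seeded 1-d k-means.
    tol : float
        EM stops when the relative log-likelihood increase drops below this.
    max_iter : int
    random_state : int or None
        Seeds the k-means initializer only.

    Attributes
    ----------
    startprob_, transmat_, means_, sds_ : fitted parameters
    sleep_state_ : index of the lower-mean (sleep) state
    loglik_path_ : per-iteration log-likelihood (non-decreasing)
    degenerate_ : True when the series was constant; scoring is skipped
    """

    def __init__(self, init: str = "quantile_split", tol: float = 1e-6,
                 max_iter: int = 200, random_state: int | None = None):
        self.init = init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _init_params(self, y):
        if self.init == "quantile_split":
            mu = np.percentile(y, [25, 75]).astype(float)
        elif self.init == "kmeans":
            km = KMeans(n_clusters=2, n_init=3,
                        random_state=self.random_state).fit(y[:, None])
            mu = np.sort(km.cluster_centers_.ravel())
        else:
            raise ValueError(f"unknown init {self.init!r}")
        if mu[1] - mu[0] < 1e-3:
            mu = mu + np.array([-0.1, 0.1])
        sd = np.full(2, max(np.std(y), _SD_FLOOR))
        pi = np.array([0.5, 0.5])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        return pi, A, mu, sd

    def fit(self, y, X=None):
        """Fit to a 1-d transformed activity series (values = log(1+MIMS))."""
        y = np.asarray(y, float).ravel()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite series")
        if len(y) < 2 or np.std(y) < 1e-10:
            self.degenerate_ = True
            self.loglik_path_ = []
            return self
        self.degenerate_ = False
        pi, A, mu, sd = self._init_params(y)
        path = []
        prev = -np.inf
        for it in range(self.max_iter):
            B = _emission_probs(y, mu, sd)
            ll, gamma, xi = _forward_backward(pi, A, B)
            if path:
                # EM guarantee, allowing a whisker for the sd floor
                assert ll >= prev - 1e-6 * max(abs(prev), 1.0), \
                    "EM log-likelihood decreased"
            path.append(ll)
            if prev > -np.inf and (ll - prev) <= self.tol * abs(prev):
                prev = ll
                break
            prev = ll
            pi = gamma[0] / gamma[0].sum()
            A = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
            w = gamma.sum(axis=0)
            mu = (gamma * y[:, None]).sum(axis=0) / w
            var = (gamma * (y[:, None] - mu[None, :]) ** 2).sum(axis=0) / w
            sd = np.maximum(np.sqrt(var), _SD_FLOOR)
        self.startprob_, self.transmat_ = pi, A
        self.means_, self.sds_ = mu, sd
        self.sleep_state_ = int(np.argmin(mu))
        self.loglik_path_ = path
        self.n_iter_ = len(path)
        self.converged_ = len(path) < self.max_iter
        return self

    def _check(self):
        if not hasattr(self, "degenerate_"):
            raise AttributeError("SleepWakeHMM is not fitted")
        if self.degenerate_:
            raise DegenerateSeriesError(
                "constant series: no two-state fit; subject should be skipped")

    def score(self, y, X=None) -> float:
        """Total log-likelihood of a series under the fitted model."""
        self._check()
        return forward_loglik(self.startprob_, self.transmat_,
                              self.means_, self.sds_, y)

    def predict_proba(self, y) -> np.ndarray:
        """Smoothed per-minute state posteriors, columns (wake, sleep)."""
        self._check()
        y = np.asarray(y, float).ravel()
        B = _emission_probs(y, self.means_, self.sds_)
        _, gamma, _ = _forward_backward(self.startprob_, self.transmat_, B)
        s = self.sleep_state_
        return np.column_stack([gamma[:, 1 - s], gamma[:, s]])

    def predict(self, y, rule: str = "posterior") -> np.ndarray:
        """Per-minute sleep labels (1 = sleep).  ``posterior`` labels sleep
        iff P(sleep) > 0.5 (ties to wake); ``viterbi`` is the MAP path."""
        self._check()
        y = np.asarray(y, float).ravel()
        if rule == "posterior":
            return (self.predict_proba(y)[:, 1] > 0.5).astype(np.int8)
        if rule == "viterbi":
            log_B = np.log(_emission_probs(y, self.means_, self.sds_))
            path = _viterbi(np.log(self.startprob_),
                            np.log(np.maximum(self.transmat_, 1e-300)), log_B)
            return (path == self.sleep_state_).astype(np.int8)
        raise ValueError(f"unknown decode rule {rule!r}")


def fit_em(y, init: str = "quantile_split", tol: float = 1e-6,
           max_iter: int = 200, seed: int | None = None) -> SleepWakeHMM:
    """Functional wrapper: fit a :class:`SleepWakeHMM` to a series."""
    return SleepWakeHMM(init=init, tol=tol, max_iter=max_iter,
                        random_state=seed).fit(y)


def decode(model: SleepWakeHMM, y, rule: str = "posterior"):
    """(labels, p_sleep) for a series under a fitted model."""
    y = np.asarray(y, float).ravel()
    p_sleep = model.predict_proba(y)[:, 1]
    labels = (p_sleep > 0.5).astype(np.int8) if rule == "posterior" \
        else model.predict(y, rule="viterbi")
    return labels, p_sleep


def score_cohort(clean: pd.DataFrame, init: str = "quantile_split",
                 tol: float = 1e-6, max_iter: int = 200,
                 rule: str = "posterior", seed: int | None = None):
    """Fit one HMM per subject on the cleaned minute series and label it.

    Returns ``(labels, models)``: the minute table with ``sleep`` and
    ``p_sleep`` columns, and a per-subject parameter table (for audit).
    Degenerate subjects are dropped from the label table and flagged in the
    model table.
    """
    frames, params = [], []
    for sid, sub in clean.groupby("subject_id", sort=False):
        sub = sub.sort_values(["day_index", "minute_of_day"],
                              kind="mergesort").reset_index(drop=True)
        y = transform_counts(sub["value"].to_numpy())
        m = fit_em(y, init=init, tol=tol, max_iter=max_iter, seed=seed)
        if m.degenerate_:
            params.append({"subject_id": sid, "degenerate": True})
            continue
        labels, p = decode(m, y, rule)
        sub["sleep"] = labels
        sub["p_sleep"] = p
        frames.append(sub)
        s = m.sleep_state_
        params.append({
            "subject_id": sid, "degenerate": False,
            "mean_sleep": m.means_[s], "mean_wake": m.means_[1 - s],
            "sd_sleep": m.sds_[s], "sd_wake": m.sds_[1 - s],
            "p_stay_sleep": m.transmat_[s, s],
            "p_stay_wake": m.transmat_[1 - s, 1 - s],
            "loglik": m.loglik_path_[-1], "n_iter": m.n_iter_,
        })
    labels_df = (pd.concat(frames, ignore_index=True)
                 if frames else pd.DataFrame())
    return labels_df, pd.DataFrame(params)
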