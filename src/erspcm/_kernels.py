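"""Numba kernels for per-cell log-likelihoods.

These loops are the sampler's hot path: every Metropolis proposal for the
person traits needs the full (n_persons, n_items) matrix of observed-cell
log-probabilities, and every threshold proposal needs one item's column.
Category probabilities use the same cumulative-logit form as
:mod:`erspcm.pcm` (max-subtracted logsumexp); agreement between the two
routes is property-tested.

Responses are passed as int64 with 0 = missing; ``ctau`` holds cumulative
threshold sums per item, ``ctau[i, k] = sum_{j<k} tau[i, j]`` (K entries,
first 0).  The plain PCM is the special case eta = 0.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["loglik_matrix", "loglik_item", "cumulative_tau", "fisher_tradeoff"]


def cumulative_tau(tau: np.ndarray) -> np.ndarray:
    """(I, J) thresholds -> (I, K) cumulative sums with leading zero."""
    tau = np.atleast_2d(tau)
    out = np.zeros((tau.shape[0], tau.shape[1] + 1))
    np.cumsum(tau, axis=1, out=out[:, 1:])
    return out


@njit(cache=True, fastmath=True)
def loglik_matrix(theta, eta, ctau, s, y, out):  # pragma: no cover - numba
    """Fill out[p, i] with log P(y_pi | theta_p, eta_p); 0 for missing."""
    n = theta.shape[0]
    I = ctau.shape[0]
    K = ctau.shape[1]
    for p in range(n):
        th = theta[p]
        et = eta[p]
        for i in range(I):
            yy = y[p, i]
            if yy < 1:
                out[p, i] = 0.0
                continue
            mx = -1e300
            for k in range(K):
                v = k * th + s[k] * et - ctau[i, k]
                if v > mx:
                    mx = v
            acc = 0.0
            for k in range(K):
                acc += np.exp(k * th + s[k] * et - ctau[i, k] - mx)
            kk = yy - 1
            out[p, i] = kk * th + s[kk] * et - ctau[i, kk] - mx - np.log(acc)


@njit(cache=True, fastmath=True)
def fisher_tradeoff(theta, eta, ctau, s, y, country, G):  # pragma: no cover - numba
    """Per-country Fisher-information sums for the (theta, eta) trade-off.

    Returns (I_tt, I_te) per country, the observed-cell sums of
    Var(k-1) and Cov(k-1, s_k) under the current category probabilities.
    The locally likelihood-flat direction is delta_theta/delta_eta =
    -I_te / I_tt.
    """
    n = theta.shape[0]
    I = ctau.shape[0]
    K = ctau.shape[1]
    out_tt = np.zeros(G)
    out_te = np.zeros(G)
    probs = np.empty(K)
    for p in range(n):
        g = country[p]
        th = theta[p]
        et = eta[p]
        for i in range(I):
            if y[p, i] < 1:
                continue
            mx = -1e300
            for k in range(K):
                v = k * th + s[k] * et - ctau[i, k]
                if v > mx:
                    mx = v
            acc = 0.0
            for k in range(K):
                probs[k] = np.exp(k * th + s[k] * et - ctau[i, k] - mx)
                acc += probs[k]
            m1 = 0.0
            ms = 0.0
            m11 = 0.0
            m1s = 0.0
            for k in range(K):
                pk = probs[k] / acc
                m1 += pk * k
                ms += pk * s[k]
                m11 += pk * k * k
                m1s += pk * k * s[k]
            out_tt[g] += m11 - m1 * m1
            out_te[g] += m1s - m1 * ms
    return out_tt, out_te


@njit(cache=True, fastmath=True)
def loglik_item(theta, eta, ctau_i, s, y_i, out):  # pragma: no cover - numba
    """Fill out[p] with log P(y_pi | ...) for a single item."""
    n = theta.shape[0]
    K = ctau_i.shape[0]
    for p in range(n):
        yy = y_i[p]
        if yy < 1:
            out[p] = 0.0
            continue
        th = theta[p]
        et = eta[p]
        mx = -1e300
        for k in range(K):
            v = k * th + s[k] * et - ctau_i[k]
            if v > mx:
                mx = v
        acc = 0.0
        for k in range(K):
            acc += np.exp(k * th + s[k] * et - ctau_i[k] - mx)
        kk = yy - 1
        out[p] = kk * th + s[kk] * et - ctau_i[kk] - mx - np.log(acc)
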