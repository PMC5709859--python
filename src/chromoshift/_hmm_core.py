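"""Numba inner loops for the Gaussian HMM: scaled forward-backward and
Viterbi. Emission log-densities are computed vectorized by the caller and
passed in as a (T, K) array; missing observations enter as all-zero rows
(their emission term marginalizes to 1)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward(startprob, transmat, log_b):
    """Scaled forward-backward for one sequence.

    Returns (loglik, gamma, xi_sum, gamma0) where gamma is (T, K) posterior
    state probabilities, xi_sum the (K, K) expected transition counts summed
    over t, and gamma0 the posterior at t=0.
    """
    T, K = log_b.shape
    # stabilize emissions per time step; the shift is absorbed into loglik
    bmax = np.empty(T)
    b = np.empty((T, K))
    for t in range(T):
        m = log_b[t, 0]
        for k in range(1, K):
            if log_b[t, k] > m:
                m = log_b[t, k]
        bmax[t] = m
        for k in range(K):
            b[t, k] = np.exp(log_b[t, k] - m)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = startprob[k] * b[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * transmat[i, j]
            alpha[t, j] = acc * b[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += transmat[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += (alpha[t, i] * transmat[i, j] * b[t + 1, j]
                                 * beta[t + 1, j] / c[t + 1])

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t]) + bmax[t]
    return loglik, gamma, xi_sum, gamma[0].copy()


@njit(cache=True)
def viterbi_path(log_startprob, log_transmat, log_b):
    """Most probable state path; ties broken toward the lower state index."""
    T, K = log_b.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_startprob[k] + log_b[0, k]
    for t in range(1, T):
        for j in range(K):
            best = delta[t - 1, 0] + log_transmat[0, j]
            arg = 0
            for i in range(1, K):
                cand = delta[t - 1, i] + log_transmat[i, j]
                if cand > best:  # strict: first (lowest) index wins ties
                    best = cand
                    arg = i
            delta[t, j] = best + log_b[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
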