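"""Numba kernels for the movement HMM.

Scaled forward/backward recursions and Viterbi over concatenated tracks.
``starts`` holds the first observation index of each track; each track uses
its own initial distribution ``delta``.  Emission probabilities arrive as
log densities ``logb`` of shape (T, S); per-step transition matrices as
``gamma`` of shape (T, S, S) (the matrix applied between t-1 and t; the row
at a track start is unused).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=False)
def forward_loglik(logb, gamma, delta, starts, ends):
    """Total log-likelihood over all tracks (scaled forward algorithm)."""
    S = logb.shape[1]
    total = 0.0
    alpha = np.empty(S)
    tmp = np.empty(S)
    for k in range(starts.shape[0]):
        t0 = starts[k]
        t1 = ends[k]
        # local shift keeps exp() in range
        m = logb[t0, 0]
        for s in range(1, S):
            if logb[t0, s] > m:
                m = logb[t0, s]
        c = 0.0
        for s in range(S):
            alpha[s] = delta[s] * np.exp(logb[t0, s] - m)
            c += alpha[s]
        if c < _TINY:
            return -1e300
        total += np.log(c) + m
        for s in range(S):
            alpha[s] /= c
        for t in range(t0 + 1, t1):
            m = logb[t, 0]
            for s in range(1, S):
                if logb[t, s] > m:
                    m = logb[t, s]
            c = 0.0
            for j in range(S):
                acc = 0.0
                for i in range(S):
                    acc += alpha[i] * gamma[t, i, j]
                tmp[j] = acc * np.exp(logb[t, j] - m)
                c += tmp[j]
            if c < _TINY:
                return -1e300
            total += np.log(c) + m
            for s in range(S):
                alpha[s] = tmp[s] / c
    return total


@njit(cache=False, fastmath=True)
def forward_loglik_cov(logb, beta0, beta_z, z, delta, starts, ends):
    """Forward log-likelihood with Gamma(z_t) built inline per step."""
    S = logb.shape[1]
    total = 0.0
    alpha = np.empty(S)
    tmp = np.empty(S)
    g = np.empty((S, S))
    for k in range(starts.shape[0]):
        t0 = starts[k]
        t1 = ends[k]
        m = logb[t0, 0]
        for s in range(1, S):
            if logb[t0, s] > m:
                m = logb[t0, s]
        c = 0.0
        for s in range(S):
            alpha[s] = delta[s] * np.exp(logb[t0, s] - m)
            c += alpha[s]
        if c < _TINY:
            return -1e300
        total += np.log(c) + m
        for s in range(S):
            alpha[s] /= c
        for t in range(t0 + 1, t1):
            zt = z[t]
            for i in range(S):
                rs = 1.0
                for j in range(S):
                    if i == j:
                        g[i, j] = 1.0
                    else:
                        e = beta0[i, j] + beta_z[i, j] * zt
                        if e > 50.0:
                            e = 50.0
                        g[i, j] = np.exp(e)
                        rs += g[i, j]
                for j in range(S):
                    g[i, j] /= rs
            m = logb[t, 0]
            for s in range(1, S):
                if logb[t, s] > m:
                    m = logb[t, s]
            c = 0.0
            for j in range(S):
                acc = 0.0
                for i in range(S):
                    acc += alpha[i] * g[i, j]
                tmp[j] = acc * np.exp(logb[t, j] - m)
                c += tmp[j]
            if c < _TINY:
                return -1e300
            total += np.log(c) + m
            for s in range(S):
                alpha[s] = tmp[s] / c
    return total


@njit(cache=False, fastmath=True)
def nll_fast(mu, sd, p0, tmean, kappa, logi0e, beta0, beta_z, z,
             log_spos, spos, zero, cos_t, sin_t, has_turn,
             delta, starts, ends):
    """Negative log-likelihood with emissions built inline (hot path)."""
    T = spos.shape[0]
    logb = np.empty((T, 3))
    log2pi = np.log(2.0 * np.pi)
    for s in range(3):
        a = (mu[s] / sd[s]) ** 2
        scale = sd[s] * sd[s] / mu[s]
        lgb = math.lgamma(a)
        la = np.log(scale)
        const = log2pi + kappa[s] + logi0e[s]
        cm = np.cos(tmean[s])
        sm = np.sin(tmean[s])
        use_p0 = p0[s] > 0.0
        lp0 = np.log(p0[s]) if use_p0 else 0.0
        l1m = np.log1p(-p0[s]) if use_p0 else 0.0
        for t in range(T):
            g = (a - 1.0) * log_spos[t] - spos[t] / scale - a * la - lgb
            if zero[t]:
                g = lp0 if use_p0 else g - 1e3
            elif use_p0:
                g += l1m
            if has_turn[t]:
                g += kappa[s] * (cos_t[t] * cm + sin_t[t] * sm) - const
            logb[t, s] = g
    return -forward_loglik_cov(logb, beta0, beta_z, z, delta, starts, ends)


@njit(cache=False)
def forward_backward(logb, gamma, delta, starts, ends):
    """Posterior state probabilities, shape (T, S)."""
    T, S = logb.shape
    post = np.empty((T, S))
    alpha = np.empty((T, S))
    for k in range(starts.shape[0]):
        t0 = starts[k]
        t1 = ends[k]
        m = np.max(logb[t0])
        c = 0.0
        for s in range(S):
            alpha[t0, s] = delta[s] * np.exp(logb[t0, s] - m)
            c += alpha[t0, s]
        for s in range(S):
            alpha[t0, s] /= c
        for t in range(t0 + 1, t1):
            m = np.max(logb[t])
            c = 0.0
            for j in range(S):
                acc = 0.0
                for i in range(S):
                    acc += alpha[t - 1, i] * gamma[t, i, j]
                alpha[t, j] = acc * np.exp(logb[t, j] - m)
                c += alpha[t, j]
            for j in range(S):
                alpha[t, j] /= c
        beta = np.ones(S)
        for s in range(S):
            post[t1 - 1, s] = alpha[t1 - 1, s]
        for t in range(t1 - 2, t0 - 1, -1):
            m = np.max(logb[t + 1])
            nb = np.empty(S)
            for i in range(S):
                acc = 0.0
                for j in range(S):
                    acc += gamma[t + 1, i, j] * np.exp(logb[t + 1, j] - m) * beta[j]
                nb[i] = acc
            c = np.sum(nb)
            for i in range(S):
                beta[i] = nb[i] / c
            tot = 0.0
            for s in range(S):
                post[t, s] = alpha[t, s] * beta[s]
                tot += post[t, s]
            for s in range(S):
                post[t, s] /= tot
    return post


@njit(cache=False)
def viterbi_path(logb, loggamma, logdelta, starts, ends):
    """Most probable state path (ties -> lowest state index)."""
    T, S = logb.shape
    path = np.empty(T, dtype=np.int64)
    score = np.empty((T, S))
    back = np.empty((T, S), dtype=np.int64)
    for k in range(starts.shape[0]):
        t0 = starts[k]
        t1 = ends[k]
        for s in range(S):
            score[t0, s] = logdelta[s] + logb[t0, s]
        for t in range(t0 + 1, t1):
            for j in range(S):
                best = score[t - 1, 0] + loggamma[t, 0, j]
                arg = 0
                for i in range(1, S):
                    v = score[t - 1, i] + loggamma[t, i, j]
                    if v > best:  # strict: ties keep lowest i
                        best = v
                        arg = i
                score[t, j] = best + logb[t, j]
                back[t, j] = arg
        best = score[t1 - 1, 0]
        arg = 0
        for s in range(1, S):
            if score[t1 - 1, s] > best:
                best = score[t1 - 1, s]
                arg = s
        path[t1 - 1] = arg
        for t in range(t1 - 2, t0 - 1, -1):
            path[t] = back[t + 1, path[t + 1]]
    return path
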