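"""Compiled scan kernels for the forward--backward recursions.

The recursions are inherently sequential in L, so they are jitted with
numba; everything around them stays in vectorised numpy.  All kernels work
on the scaled (normalised-message) representation: ``alpha[l]`` is the
filtering distribution at position l and ``c[l]`` the per-position scaling
factor, so ``sum(log c)`` recovers the marginal log-likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def forward_scaled(b, P, pi):
    """Scaled forward pass.

    b : (L, K) emission likelihoods up to a per-row constant
    Returns (alpha, c): normalised forward messages and scaling factors.
    """
    L, K = b.shape
    alpha = np.empty((L, K))
    c = np.empty(L)
    acc = 0.0
    for k in range(K):
        v = pi[k] * b[0, k]
        alpha[0, k] = v
        acc += v
    c[0] = acc
    for k in range(K):
        alpha[0, k] /= acc
    for l in range(1, L):
        acc = 0.0
        for k in range(K):
            pred = 0.0
            for j in range(K):
                pred += alpha[l - 1, j] * P[j, k]
            v = pred * b[l, k]
            alpha[l, k] = v
            acc += v
        c[l] = acc
        for k in range(K):
            alpha[l, k] /= acc
    return alpha, c


@njit(cache=False)
def backward_smooth(alpha, b, P, c):
    """Scaled backward pass; returns the smoothing probabilities gamma."""
    L, K = alpha.shape
    gamma = np.empty((L, K))
    beta = np.ones(K)
    for k in range(K):
        gamma[L - 1, k] = alpha[L - 1, k]
    for l in range(L - 2, -1, -1):
        nb = np.empty(K)
        for j in range(K):
            s = 0.0
            for k in range(K):
                s += P[j, k] * b[l + 1, k] * beta[k]
            nb[j] = s / c[l + 1]
        tot = 0.0
        for k in range(K):
            v = alpha[l, k] * nb[k]
            gamma[l, k] = v
            tot += v
        # rows are normalised already up to rounding; renormalise anyway
        for k in range(K):
            gamma[l, k] /= tot
        beta = nb
    return gamma


@njit(cache=False)
def sample_path_from_messages(alpha, P, u):
    """Backward sampling of a hidden path given forward messages.

    u : (L,) iid Uniform(0,1) variates consumed from the end backwards.
    Returns the sampled path (0-based labels).
    """
    L, K = alpha.shape
    path = np.empty(L, dtype=np.int64)
    # terminal state ~ alpha[L-1]
    r = u[L - 1]
    acc = 0.0
    s = K - 1
    for k in range(K):
        acc += alpha[L - 1, k]
        if r <= acc:
            s = k
            break
    path[L - 1] = s
    for l in range(L - 2, -1, -1):
        tot = 0.0
        for k in range(K):
            tot += alpha[l, k] * P[k, path[l + 1]]
        r = u[l] * tot
        acc = 0.0
        s = K - 1
        for k in range(K):
            acc += alpha[l, k] * P[k, path[l + 1]]
            if r <= acc:
                s = k
                break
        path[l] = s
    return path


@njit(cache=False)
def transition_counts(path, K):
    """K x K matrix of observed transition counts along a path."""
    C = np.zeros((K, K), dtype=np.int64)
    for l in range(path.shape[0] - 1):
        C[path[l], path[l + 1]] += 1
    return C


@njit(cache=False)
def simulate_path(P, pi, L, u):
    """Draw a hidden path: theta_0 ~ pi, theta_{l+1} ~ P[theta_l]."""
    path = np.empty(L, dtype=np.int64)
    K = P.shape[0]
    r = u[0]
    acc = 0.0
    s = K - 1
    for k in range(K):
        acc += pi[k]
        if r <= acc:
            s = k
            break
    path[0] = s
    for l in range(1, L):
        r = u[l]
        acc = 0.0
        s = K - 1
        for k in range(K):
            acc += P[path[l - 1], k]
            if r <= acc:
                s = k
                break
        path[l] = s
    return path
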