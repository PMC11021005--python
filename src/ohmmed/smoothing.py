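"""Forward--backward smoothing and conditional path sampling.

Implements the scaled (normalised-message) variant of the forward and
backward recursions: forward messages are renormalised at every position
and the log of the scaling factors accumulated, which keeps the recursion
stable for sequences of millions of windows while recording a per-position
numerical audit trail.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._rng import as_rng
from .model_core import TransitionMatrix

__all__ = ["SmoothingResult", "forward_backward", "sample_hidden_path", "position_posterior_mean"]


@dataclass
class SmoothingResult:
    """Posterior state probabilities and marginal likelihood of a sequence.

    gamma : (L, K) smoothing probabilities Pr(theta_l = i | y)
    loglik : natural-log marginal likelihood of the observations
    scalings : (L,) per-position scaling factors from the forward pass
    forward_messages : (L, K) normalised filtering distributions, kept so
        that a backward sampling pass can draw full hidden paths from the
        exact conditional Pr(theta | y).
    """

    gamma: np.ndarray
    loglik: float
    scalings: np.ndarray
    forward_messages: np.ndarray
    P: np.ndarray


def _as_P(P) -> np.ndarray:
    return P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)


def forward_backward(logdens, P, pi) -> SmoothingResult:
    """Run the scaled forward--backward recursions.

    Parameters
    ----------
    logdens : (L, K) array
        Per-position, per-state emission log densities.
    P : TransitionMatrix or (K, K) array
    pi : (K,) initial state distribution (the chain's stationary law).

    Raises
    ------
    ValueError
        On shape mismatch, or if some position has ``-inf`` in every
        state (the observation is impossible under the model); such
        positions must be handled upstream, not silently skipped.
    """
    P = _as_P(P)
    logdens = np.asarray(logdens, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if logdens.ndim != 2:
        raise ValueError("logdens must be L x K")
    L, K = logdens.shape
    if P.shape != (K, K) or pi.shape != (K,):
        raise ValueError(
            f"shape mismatch: logdens is {logdens.shape}, P {P.shape}, pi {pi.shape}"
        )
    row_max = np.max(logdens, axis=1)
    if np.any(np.isneginf(row_max)):
        bad = int(np.nonzero(np.isneginf(row_max))[0][0])
        raise ValueError(f"position {bad} impossible under every state (-inf log density)")
    b = np.exp(logdens - row_max[:, None])
    b = np.ascontiguousarray(b)
    alpha, c = _kernels.forward_scaled(b, np.ascontiguousarray(P), np.ascontiguousarray(pi))
    loglik = float(np.sum(np.log(c)) + np.sum(row_max))
    gamma = _kernels.backward_smooth(alpha, b, P, c)
    return SmoothingResult(gamma=gamma, loglik=loglik, scalings=c, forward_messages=alpha, P=P)


def forward_only(logdens, P, pi):
    """Forward pass alone: (forward messages, scalings, loglik).

    Cheaper than :func:`forward_backward` when only the likelihood and a
    sampled path are needed (the Gibbs sweep's common case).
    """
    P = _as_P(P)
    logdens = np.asarray(logdens, dtype=float)
    row_max = np.max(logdens, axis=1)
    if np.any(np.isneginf(row_max)):
        bad = int(np.nonzero(np.isneginf(row_max))[0][0])
        raise ValueError(f"position {bad} impossible under every state (-inf log density)")
    b = np.ascontiguousarray(np.exp(logdens - row_max[:, None]))
    alpha, c = _kernels.forward_scaled(b, np.ascontiguousarray(P), np.ascontiguousarray(np.asarray(pi, dtype=float)))
    loglik = float(np.sum(np.log(c)) + np.sum(row_max))
    return alpha, c, loglik


def sample_hidden_path(messages, P, seed=None) -> np.ndarray:
    """Draw a full hidden path from Pr(theta | y) by backward sampling.

    ``messages`` is either a :class:`SmoothingResult` or the (L, K) array
    of normalised forward messages produced with the same ``P``.  Under a
    tridiagonal ``P`` every sampled path moves only between neighbouring
    states.  Reproducible given a seed or Generator.
    """
    if isinstance(messages, SmoothingResult):
        if P is None:
            P = messages.P
        alpha = messages.forward_messages
    else:
        alpha = np.asarray(messages, dtype=float)
    P = _as_P(P)
    if alpha.shape[1] != P.shape[0]:
        raise ValueError("forward messages and transition matrix disagree on K")
    rng = as_rng(seed)
    u = rng.random(alpha.shape[0])
    return _kernels.sample_path_from_messages(alpha, P, u)


def position_posterior_mean(gamma, state_means) -> np.ndarray:
    """Posterior-mean track: ``out[l] = sum_i gamma[l, i] * mean_i``.

    This is the smoothed value sequence used for cross-feature
    correlations; it always lies within [min(mean), max(mean)].
    """
    gamma = np.asarray(gamma, dtype=float)
    state_means = np.asarray(state_means, dtype=float)
    if gamma.ndim != 2 or gamma.shape[1] != state_means.shape[0]:
        raise ValueError(
            f"dimension mismatch: gamma {gamma.shape}, means length {state_means.shape[0]}"
        )
    return gamma @ state_means
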