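"""Shared fixtures and independent oracles.

The enumeration oracle computes HMM marginals by brute force over all K^L
hidden paths; it shares no code with the scaled recursions it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from ohmmed.gibbs import FitResult


def enumerate_forward_backward(logdens, P, pi):
    """Brute-force marginal loglik and smoothing probabilities.

    Sums the joint probability of every possible hidden path; only viable
    for K^L up to a few thousand.
    """
    L, K = logdens.shape
    log_P = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), -np.inf)
    log_pi = np.where(pi > 0, np.log(np.where(pi > 0, pi, 1.0)), -np.inf)
    log_joint = []
    paths = list(itertools.product(range(K), repeat=L))
    for path in paths:
        lp = log_pi[path[0]] + logdens[0, path[0]]
        for l in range(1, L):
            lp += log_P[path[l - 1], path[l]] + logdens[l, path[l]]
        log_joint.append(lp)
    log_joint = np.array(log_joint)
    m = np.max(log_joint)
    w = np.exp(log_joint - m)
    loglik = m + np.log(np.sum(w))
    gamma = np.zeros((L, K))
    for lp, path in zip(w, paths):
        for l, s in enumerate(path):
            gamma[l, s] += lp
    gamma /= np.sum(w)
    return loglik, gamma


@pytest.fixture
def enum_oracle():
    return enumerate_forward_backward


def make_fit(params, occupancy, gamma=None, hard=None, config=None):
    """Assemble a FitResult around known parameters (no MCMC).

    Used by diagnostics tests that need a fit object with exactly known
    emission parameters and occupancies.
    """
    K = params.K
    if hasattr(params, "sd"):
        family = "normal"
        rows = [{"parameter": f"mean_{i + 1}", "mean": params.means[i]} for i in range(K)]
        rows.append({"parameter": "sd", "mean": params.sd})
    else:
        family = "gamma-poisson"
        rows = [{"parameter": "shape", "mean": params.shape}]
        rows += [{"parameter": f"rate_{i + 1}", "mean": params.rates[i]} for i in range(K)]
    summary = pd.DataFrame(rows)
    for col in ("median", "sd", "q2.5", "q97.5"):
        if col not in summary:
            summary[col] = np.nan
    if gamma is None:
        gamma = np.tile(np.asarray(occupancy, float), (4, 1))
    if hard is None:
        hard = np.argmax(gamma, axis=1)
    means = np.asarray(params.state_means, float)
    return FitResult(
        family=family,
        K=K,
        summary=summary,
        gamma_mean=np.asarray(gamma, float),
        hard_assignment=np.asarray(hard),
        posterior_mean_track=np.asarray(gamma, float) @ means,
        occupancy=np.asarray(occupancy, float),
        mean_run_length=np.full(K, np.nan),
        P_mean=np.eye(K),
        state_means=means,
        state_sds=np.asarray(params.state_sds, float),
        config=config,
    )


@pytest.fixture
def fit_factory():
    return make_fit
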