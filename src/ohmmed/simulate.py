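"""Generative model: hidden paths and emissions with ground truth retained.

The simulator is the exact generative counterpart of the inference model:
a stationary tridiagonal Markov chain over ordered states, emitting either
normals with a shared standard deviation or Poisson counts whose
intensities are drawn from state-specific gammas.  It is used both as a
fixture generator for tests and as a power/calibration tool for the
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._rng import as_rng
from .emissions import GammaPoissonEmissionParams, NormalEmissionParams
from .model_core import TransitionMatrix, stationary_distribution

__all__ = ["SimulatedSequence", "simulate_sequence"]


@dataclass
class SimulatedSequence:
    """A simulated track with its hidden ground truth.

    path : (L,) true hidden states (0-based)
    y : (L,) observed values (reals for the normal family, integer counts
        for gamma-Poisson)
    latent_rates : (L,) true Poisson intensities (gamma-Poisson only)
    """

    path: np.ndarray
    y: np.ndarray
    latent_rates: np.ndarray | None = None


def simulate_sequence(P, params, L: int, seed=None, start_state: int | None = None) -> SimulatedSequence:
    """Simulate ``L`` windows from the ordered HMM.

    The initial state is drawn from the stationary distribution of ``P``
    (matching the model's reversibility prior) unless ``start_state``
    overrides it.  For the gamma-Poisson family the latent intensities are
    returned so sampler internals can be tested against ground truth.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not isinstance(P, TransitionMatrix):
        P = TransitionMatrix(np.asarray(P, dtype=float))
    rng = as_rng(seed)
    pi = stationary_distribution(P)
    u = rng.random(L)
    if start_state is not None:
        pi = np.zeros(P.K)
        pi[start_state] = 1.0
    path = _kernels.simulate_path(np.ascontiguousarray(P.P), pi, L, u)

    if isinstance(params, NormalEmissionParams):
        y = rng.normal(loc=params.means[path], scale=params.sd)
        return SimulatedSequence(path=path, y=y)
    if isinstance(params, GammaPoissonEmissionParams):
        lam = rng.gamma(shape=params.shape, scale=1.0 / params.rates[path])
        y = rng.poisson(lam)
        return SimulatedSequence(path=path, y=y, latent_rates=lam)
    raise TypeError(f"unknown emission parameter type {type(params)!r}")
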